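# dxcriteria

Computable clinical diagnostic criteria: parse QDM/HQMF criterion
documents, populate OWL ontologies, and generate SWRL rules.

Clinical diagnostic criteria ("LDL-c below 100 mg/dL", "INR of at least
2") are usually published as free text, which makes them impossible to
execute against electronic health records. `dxcriteria` implements a
standards-based translation pipeline for the common laboratory-test
pattern of such criteria:

1. **Upper ontology.** A diagnostic-criteria upper ontology merges the
   ICD-11 content model (the 13 parameters that describe a disease entity,
   plus the manifestation sub-elements *Investigation Findings* and *Signs
   and Symptoms*) with the 10 Quality Data Model (QDM) datatypes most used
   in diagnostic criteria — e.g. `Laboratory Test, Result ⊑ Investigation
   Findings`. Three support classes (`Patient`, `Unit`, `Evidence`), six
   object properties (`has_result`, `has_method`, `has_reason`,
   `has_severity`, `has_unit`, `has_evidence`) and one data property
   (`has_value`) complete the schema.
2. **HQMF parsing.** Criteria serialized in HL7 HQMF R1 XML are parsed
   into structured objects: the datatype template OID, the value-set name
   and OID, and the result constraint (an `IVL_PQ` interval, a coded
   value, or bare presence).
3. **Ontology population.** Each criterion extends a copy of the upper
   ontology into a disease-specific domain ontology: the value set becomes
   a subclass of its datatype, terminology codes become annotations, and
   units become individuals of `Unit`.
4. **SWRL rule generation.** Each criterion compiles to one rule,
   body → head, over seven atom kinds. For a numeric criterion
   *name OP threshold [unit]*:

   ```
   Patient(?x), C(?y), has_result_comparison(?x, ?y),
   has_value(?y, ?z), int(?z), has_unit(?y, u),
   OP(?z, threshold) -> has_evidence(?x, ev_i)
   ```

   where `OP ∈ {lessThan, lessThanOrEqual, greaterThan,
   greaterThanOrEqual, equal}` follows the interval bound and its
   inclusivity flag. Rules are syntax-validated (identifier legality, the
   SWRL safety condition, atom arities, known built-ins, non-empty head)
   and can be evaluated against toy fact sets by single-rule forward
   chaining.

## Worked example

```python
from dxcriteria import (build_dcuo, parse_hqmf_document, populate_dcdo,
                        compose_rule, render_rule, validate_rule)
from dxcriteria.examples import example_lab_document

(criterion,) = parse_hqmf_document(example_lab_document())
print(criterion.title)
dcdo, edits = populate_dcdo(build_dcuo(), [criterion])
rule = compose_rule(criterion, dcdo, 1)
print(render_rule(rule))
print(validate_rule(rule).valid)
```

prints

```
Laboratory Test, Result: LDL-c (result < 100 mg/dL)
Patient(?x), LDL-c(?y), has_result_comparison(?x, ?y), has_value(?y, ?z), int(?z), has_unit(?y, mg/dL), lessThan(?z, 100) -> has_evidence(?x, ev1)
True
```

The criterion's high bound of 100 (exclusive) became the strict
`lessThan` built-in, `mg/dL` became a unit individual, and the head
asserts the per-rule evidence individual `ev1`: any patient `?x` linked
to an LDL-c observation whose value in mg/dL is below 100 satisfies the
criterion.

The same flow from the shell, over the packaged 15-criterion laboratory
corpus:

```bash
dxcriteria gen-fixtures --out fixtures/          # 15 HQMF XML files
dxcriteria run --criteria src/dxcriteria/data/lab_criteria.txt --out out/
# 15 criteria -> 15 rules: 14 valid, 1 invalid
```

`out/report.json` shows that the one invalid rule is the HIV viral-load
criterion: its UCUM unit `[copies]/mL` contains square brackets, which
are illegal in SWRL identifiers (`ILLEGAL_CHAR`). The other artifacts are
the upper ontology (`dcuo.owl`), the populated domain ontology
(`dcdo.owl`), the rules as canonical text (`rules.swrl.txt`) and embedded
in OWL with the SWRL RDF vocabulary (`dcdo_rules.owl`), and the
population edit log (`edits.jsonl`).

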