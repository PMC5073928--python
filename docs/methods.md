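# Methods

This note documents the models, mapping rules and design choices behind
`dxcriteria`, and what the test suite does and does not establish.

## The upper ontology

The upper ontology (`ontology_core.build_dcuo`) is a fixed, deterministic
structure merging two standard information models.

**ICD-11 content model.** The 13 main parameters of the content model
(entity title, classification properties, textual definitions, terms,
body system/structure description, temporal properties, severity-of-
subtypes properties, manifestation properties, causal properties,
functioning properties, specific condition properties, treatment
properties, diagnostic criteria) are root classes with prefix `ICD`. Two
manifestation sub-elements — *Investigation Findings* and *Signs and
Symptoms* — are subclasses of *Manifestation Properties*; they are the
elements that laboratory and symptom criteria attach to. The entity-title
parameter is modeled as the class `Title`, since it is the subsumer of
the `Diagnostic, Active` datatype. No attempt is made to reconstruct the
full content-model class inventory beyond these 15 named classes: only
the derivable counts (10 QDM datatypes, 3 support classes, 6 object
properties, 1 data property) are treated as invariants.

**QDM datatypes.** The 10 QDM datatypes commonly used in diagnostic
criteria are subclasses (prefix `QDM`) of their content-model elements:

| QDM datatype | parent |
|---|---|
| Laboratory Test, Result | Investigation Findings |
| Diagnostic Study, Performed | Investigation Findings |
| Diagnostic, Active | Title |
| Physical Exam, Performed | Investigation Findings |
| Symptom, Active | Signs and Symptoms |
| Medication, Active | Treatment Properties |
| Patient Characteristic Birth Date | Specific Condition Properties |
| Patient Characteristic Race | Specific Condition Properties |
| Patient Characteristic Sex | Specific Condition Properties |
| Procedure, Recommended | Treatment Properties |

The four QDM attributes (result, method, reason, severity) become the
object properties `has_result`, `has_method`, `has_reason`,
`has_severity`; `has_unit` and `has_evidence` support rule construction,
and `has_value` is the single data property. `Patient`, `Unit` and
`Evidence` (prefix `DCUO`) are modeled as root classes; their placement
is a design choice, as is every namespace IRI
(`https://w3id.org/dxcriteria/{icd,qdm,dcuo,dcdo}#`).

**Identifiers.** Display names become identifiers by replacing whitespace
runs and parentheses with single underscores (collapsed, trailing
trimmed); commas are kept (`Laboratory_Test,_Result`), applied uniformly.
Square brackets are deliberately *preserved*: bracketed UCUM units such
as `[copies]/mL` must survive into the ontology so that rule validation —
not name mangling — rejects them. `sanitize_name` is idempotent and
rejects names that reduce to nothing.

**Serialization.** Ontologies are plain data structures; OWL 2 I/O goes
through rdflib (RDF/XML and Turtle). Round trips preserve classes,
properties, individuals, annotations, labels and parent links; local
names are percent-encoded in IRIs so commas, slashes and brackets
survive. rdflib's element ordering varies with the per-process hash seed,
so RDF/XML output is canonicalized (subject and property elements sorted)
to keep pipeline output byte-stable across runs.

## HQMF parsing and fixture generation

Parsing (`hqmf_io`) is namespace-agnostic on local element names and
supports six HQMF R1 template OIDs: three criterion templates
(`…3.560.1.12` Laboratory Test, Result; `…1.402` Patient Characteristic
Sex; `…1.400` Patient Characteristic Birth Date) and three nested result
templates (`…1019.1` result/is-present, `…1019.2` result/value-set,
`…1019.3` result/comparison). Any other templateId raises — unknown
templates are never skipped silently. Result observations always attach
to their host criterion and are never emitted standalone. Criterion
titles decode XML entities, strip an optional `Occurrence X of ` prefix
(recorded as metadata; it does not change the generated logic), split at
the first colon (datatype names contain commas, never colons), and strip
a trailing `(result …)` clause from the value-set name. The value-set
class name is taken from the title; the inner `code/@displayName`
("LDL-c LOINC Value Set") is kept as metadata only.

Only the laboratory and result-comparison template shapes are published;
the sex, birth-date, is-present and value-set fixtures follow the same
skeleton by analogy and are labelled synthetic. A both-bounds `IVL_PQ`
interval is collapsed to a single value (only the degenerate equal-bounds
case, produced by equality criteria, is generated).

The textual grammar (`criteria_text`) covers
`[Occurrence X of ] DATATYPE: NAME (result OP NUM [UNIT])` and
`… (result: 'TERM')`, with comparison tokens accepted with or without an
internal space (`> =` ≡ `>=`). Rendering to HQMF maps `lt/le` to a high
bound (inclusive false/true), `gt/ge` to a low bound, and `eq` to a
degenerate equal-bounds interval (included for closure; the corpus never
uses it). Units may contain spaces (`per mm3`). Display units are mapped
to UCUM where they differ — the single mapping is `copies/mL →
[copies]/mL` — and inverted when recovering the textual form, so
`parse(render(spec)) = spec` holds exactly while the bracketed UCUM unit
still reaches the ontology and fails validation. Value-set OIDs are not
part of the textual form; rendered documents carry deterministic
sha1-derived OIDs under a dedicated arc, marked synthetic in the fixture
manifest.

The random generator draws, per criterion: with probability
`bracket_unit_prob` (default 0) a numeric comparison with a bracketed
UCUM unit; otherwise nominal with probability 0.3; otherwise a numeric
comparison with a unit absent 20% of the time and a non-integral
threshold 25% of the time. It is deterministic given its seed. It
emulates single laboratory-style criteria only — no temporal logic, no
AND/OR composition across criteria, no real value-set content — so
passing round-trip and oracle tests demonstrate correctness of the
translation machinery, not coverage of full eCQM logic.

## Domain-ontology population

`populate_dcdo` extends a *copy* of the upper ontology (the input is
never mutated) by, per criterion: the sanitized value-set name as a
subclass of its QDM datatype class (prefix `DCDO`); the datatype-level
coded concept as annotations (`code`, `displayName`, `codeSystem`) of the
datatype class, per the published mapping rule that attaches them to the
class itself; `valueSetOID`, the value-set code system
`2.16.840.1.113883.3.560.101.1` and the display name as annotations of
the new class; for numeric comparisons, `has_result_comparison` as a
sub-property of `has_result` (with the SNOMED-CT concept 385676005
"result" annotating `has_result` and `valueType IVL_PQ` annotating the
comparison property); units as individuals of `Unit`; thresholds logged
as uses of `has_value`. Nominal result values become individuals of an
artifact class `ResultValue`. The annotation property keys themselves
(`code`, `codeSystem`, `codeSystemName`, `displayName`, `valueSetOID`,
`valueType`) are this implementation's names; only their values are
standard.

`has_result_comparison` lives in the domain ontology, not the upper
ontology, keeping the upper ontology at exactly six object properties.
Population is monotone (the upper ontology is a subgraph of every domain
ontology) and idempotent at the ontology level; the edit log records only
actual changes, except that data-property *uses* are usage records, not
ontology elements, and recur on replay.

## Rule composition, validation, evaluation

Body atom order is fixed — `Patient(?x)`, value-set class `(?y)`,
patient–observation link, `has_value(?y, ?z)`, data range, unit,
comparison built-in — so rendered rules are deterministic and golden
strings are stable. Numeric criteria link patient and observation via
`has_result_comparison`; nominal and is-present criteria use
`has_result`, with nominal values additionally asserted as
`has_result(?y, value)` (the published material gives no nominal worked
example; this is the package's choice). The data-range atom is `int(?z)`
for integral thresholds and `decimal(?z)` otherwise. The head is always
`has_evidence(?x, ev{i})` with one evidence individual per rule index.
`same_individual`/`different_individual` atoms are representable and
evaluable but never emitted.

Validation performs five checks, in order: identifier legality (no `[`,
`]` or whitespace in predicates or named-individual arguments), the SWRL
safety condition (head variables must occur in the body), atom arity
(unary for class and data-range atoms, binary otherwise), membership of
built-ins in the supported comparison set (`lessThan`, `lessThanOrEqual`,
`greaterThan`, `greaterThanOrEqual`, `equal`, `notEqual`), and a
non-empty head. This is a minimal reconstruction of editor-style SWRL
grammar checking, chosen as the smallest rule set that is sound on
bracket-free input; it reports machine-readable violation codes rather
than raising.

`evaluate_rule` is a deliberately naive single-rule forward chainer over
toy fact sets: left-to-right join of body atoms over explicit class,
property and data assertions, with exact unit-individual matching, no
class subsumption and no recursion. It exists as a semantic oracle for
composed rules, and the suite checks it against an independent
brute-force predicate evaluator over ~400 random criterion/fact-set
pairs, including boundary values (value equal to threshold),
non-integral values against `int(?z)`, wrong units and unlinked
observations. It is not a reasoner and makes no claim about OWL-DL
semantics.

Rules serialize both as canonical text (comma-separated atoms, a single
`" -> "` separator, `?`-prefixed variables) and embedded in the domain
ontology with the standard SWRL RDF vocabulary (`swrl:Imp`, typed atom
nodes, `swrlb:` built-ins, `urn:swrl#` variables); blank-node labels are
minted deterministically per rule.

## Pipeline and problem sizes

The CLI wires the stages end to end and is fully deterministic:
re-running on identical inputs produces byte-identical artifacts. Exit
status is 0 when every rule validates, 2 when any fails (suppressible
with `--no-strict`), 1 on hard errors.

The packaged study inputs are the published ones: one worked-example
laboratory criterion document, a 15-criterion laboratory corpus (expected
outcome: 15 rules, 14 valid, one `ILLEGAL_CHAR` failure on
`[copies]/mL`), and six template fixtures. Property tests use 200
examples per property and the acceptance script round-trips 200 random
criteria; these sizes were chosen as comfortably sufficient to exercise
every branch of the grammar and fact-set generators.

## Known limitations

- Only the six listed HQMF template OIDs are supported; HQMF R2 and the
  remaining template inventory are out of scope.
- No aggregation of per-criterion rules with logical or temporal
  operators; one criterion yields one rule. Negation and disjunction are
  not expressible in SWRL at all.
- No description-logic reasoning or consistency checking over the
  produced ontologies; no value-set resolution against terminology
  services (value-set OIDs from textual input are synthetic).
- Birth-date criteria are carried through the generic numeric path
  (an age comparison on `has_value`); deriving age from the birth date
  itself is not modeled.
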