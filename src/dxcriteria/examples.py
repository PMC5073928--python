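"""Packaged worked-example inputs.

* :func:`example_lab_document` — an HQMF R1 document for the criterion
  "Laboratory Test, Result: LDL-c (result < 100 mg/dL)", the standard
  worked example of the laboratory-result and result-comparison templates.
* :func:`example_criteria_text` — a 15-criterion laboratory corpus (one
  criterion per line in the textual grammar) used for the end-to-end
  rule-generation experiment; 14 of the 15 yield syntactically valid rules
  and one (HIV Viral Load, UCUM unit "[copies]/mL") fails identifier
  validation.
"""

from importlib.resources import files


def example_lab_document() -> str:
    """The LDL-c laboratory criterion as HQMF R1 XML."""
    return files("dxcriteria").joinpath("data/ldl_criterion.xml").read_text("utf-8")


def example_criteria_text() -> str:
    """The 15-criterion laboratory corpus, one criterion per line."""
    return files("dxcriteria").joinpath("data/lab_criteria.txt").read_text("utf-8")
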