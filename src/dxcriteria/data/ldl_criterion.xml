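<?xml version="1.0" encoding="UTF-8"?>
<QualityMeasureDocument xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance">
  <!-- Laboratory Test, Result pattern -->
  <templateId root="2.16.840.1.113883.3.560.1.12"/>
  <id root="c5244e91-3c2e-4863-ae87-a48556b9e3ae"/>
  <code code="30954-2" displayName="Results" codeSystem="2.16.840.1.113883.6.1"/>
  <sourceOf typeCode="COMP">
    <observation classCode="OBS" moodCode="EVN" isCriterionInd="true">
      <code code="2.16.840.1.113883.3.117.1.7.1.215" displayName="LDL-c LOINC Value Set" codeSystem="2.16.840.1.113883.3.560.101.1"/>
      <title>Laboratory Test, Result: LDL-c (result &lt; 100 mg/dL)</title>
      <statusCode code="completed"/>
      <sourceOf typeCode="REFR">
        <observation classCode="OBS" moodCode="EVN" isCriterionInd="true">
          <templateId root="2.16.840.1.113883.3.560.1.1019.3"/>
          <code code="385676005" codeSystem="2.16.840.1.113883.6.96" displayName="result" codeSystemName="SNOMED-CT"/>
          <value xsi:type="IVL_PQ">
            <high value="100" unit="mg/dL" inclusive="false"/>
          </value>
        </observation>
      </sourceOf>
    </observation>
  </sourceOf>
</QualityMeasureDocument>
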