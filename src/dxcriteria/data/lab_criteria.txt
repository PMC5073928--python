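# Laboratory-test criterion corpus: 15 criteria drawn from published
# electronic clinical quality measures, all using the QDM datatype
# "Laboratory Test, Result".  One criterion per line.
Laboratory Test, Result: INR (result > = 2)
Laboratory Test, Result: Hospital Measures-Neutrophil count (result < 500 per mm3)
Laboratory Test, Result: High Density Lipoprotein (HDL) (result < 40 mg/dL)
Laboratory Test, Result: Hepatitis A Antigen Test (result: 'Seropositive')
Laboratory Test, Result: Hepatitis B Antigen Test (result: 'Seropositive')
Laboratory Test, Result: HIV Viral Load (result < 200 copies/mL)
Occurrence A of Laboratory Test, Result: High Density Lipoprotein (HDL) (result < 60 mg/dL)
Occurrence A of Laboratory Test, Result: LDL Code (result < 100 mg/dL)
Occurrence A of Laboratory Test, Result: LDL-C Laboratory Test (result < 100 mg/dL)
Laboratory Test, Result: Macroalbumin Test (result: 'Positive Finding')
Laboratory Test, Result: Mumps Antigen Test (result: 'Seropositive')
Laboratory Test, Result: Prostate Specific Antigen Test (result < = 10 ng/mL)
Laboratory Test, Result: Measles Antigen Test (result: 'Seropositive')
Laboratory Test, Result: Rubella Antigen Test (result: 'Seropositive')
Laboratory Test, Result: High Density Lipoprotein (HDL) (result < 40 mg/dL)
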