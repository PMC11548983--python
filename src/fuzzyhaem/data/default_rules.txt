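# fuzzyhaem default rule base, version 1.0
#
# Reconstructed from the classical MCV/RDW anemia classification matrix
# (red-cell size crossed with size heterogeneity), with Hb/PCV rules for
# polycythemia, dehydration, generic anemia and the all-normal case.
# ABSENT rules are implicit: absent = 1 - present unless overridden.
#
# All-normal panel
IF MCV IS NORMAL AND RDW IS NORMAL AND HB IS NORMAL AND PCV IS NORMAL THEN D0 IS PRESENT
#
# Microcytic, uniform cell size, anemic: thalassemia carrier / anemia of
# chronic disease (D1 also fires on the normocytic branch below)
IF MCV IS LOW AND RDW IS NORMAL AND HB IS LOW THEN D1 IS PRESENT
IF MCV IS NORMAL AND RDW IS NORMAL AND HB IS LOW THEN D1 IS PRESENT
IF MCV IS LOW AND RDW IS NORMAL AND HB IS LOW THEN D2 IS PRESENT
#
# Microcytic with anisocytosis: iron deficiency / Hb H disease / sickle
# cell beta thalassemia
IF MCV IS LOW AND RDW IS HIGH THEN D3 IS PRESENT
IF MCV IS LOW AND RDW IS HIGH THEN D4 IS PRESENT
IF MCV IS LOW AND RDW IS HIGH THEN D5 IS PRESENT
#
# Macrocytic, uniform cell size, anemic: myelodysplastic syndrome /
# aplastic anemia
IF MCV IS HIGH AND RDW IS NORMAL AND HB IS LOW THEN D6 IS PRESENT
IF MCV IS HIGH AND RDW IS NORMAL AND HB IS LOW THEN D7 IS PRESENT
#
# Macrocytic with anisocytosis: megaloblastic / immune hemolytic anemia
IF MCV IS HIGH AND RDW IS HIGH THEN D8 IS PRESENT
IF MCV IS HIGH AND RDW IS HIGH THEN D9 IS PRESENT
#
# Normocytic with anisocytosis: megaloblastic (early) / sideroblastic /
# myelofibrosis / sickle cell anemia
IF MCV IS NORMAL AND RDW IS HIGH THEN D8 IS PRESENT
IF MCV IS NORMAL AND RDW IS HIGH THEN D12 IS PRESENT
IF MCV IS NORMAL AND RDW IS HIGH THEN D13 IS PRESENT
IF MCV IS NORMAL AND RDW IS HIGH THEN D14 IS PRESENT
#
# Normocytic, uniform cell size, anemic: sickle cell trait / hereditary
# spherocytosis
IF MCV IS NORMAL AND RDW IS NORMAL AND HB IS LOW THEN D10 IS PRESENT
IF MCV IS NORMAL AND RDW IS NORMAL AND HB IS LOW THEN D11 IS PRESENT
#
# Hb/PCV-driven labels
IF HB IS HIGH AND PCV IS HIGH THEN D15 IS PRESENT
IF PCV IS HIGH THEN D16 IS PRESENT
IF HB IS LOW THEN D17 IS PRESENT
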