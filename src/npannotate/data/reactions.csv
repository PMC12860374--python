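name,plus,minus,phase,max_multiplicity
+2H,H2,,I,1
-2H,,H2,I,1
+O,O,,I,2
-H2O,,H2O,I,1
+H2O,H2O,,I,1
+CH2,CH2,,II,3
-CH2,,CH2,I,1
+SO3,SO3,,II,2
+GluA,C6H8O6,,II,2
+Glc,C6H10O5,,II,1
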