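@r01_short_header
ACGTACG
+
IIIIIII
@r02_short_header
ACG
+
III
@r03_bad_barcode
AAATTTTTTCCCCCCCCCCCCCCCCCCCC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r04_bad_barcode
AAAAATTTTTTTTTTTTTTTTTTTTTTTT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r05_tooshort_u1c
AAAACGTTTCTCTCTCTCTAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r06_tooshort_u70k
AAACATGTTTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r07_tooshort_wt
AAAGTCATTCCTTCCTTCCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r08_tooshort_u1c
AAAACGTTTCTTCTTCTTCTTCT
+
IIIIIIIIIIIIIIIIIIIIIII
@r09_tooshort_u70k
AAACATGTTTTCCTTCCTTCCTT
+
IIIIIIIIIIIIIIIIIIIIIII
@r10_tooshort_u1c
AAAACGTTTCCTCCTCCTCCTAGATC
+
IIIIIIIIIIIIIIIIIIIIIIIIII
@r11_pass_u1c
AAAACGTTTCTCTCTCTCTCTCTCTCTCTAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r12_pass_u1c
AAAACGTTTCTCTCTCTCTCTCTCTCTCTAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r13_pass_u1c
AAAACGTTTCTCTCTCTCTCTCTCTCTCTAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r14_pass_u1c
AAAACGTTTCTCTCTCTCTCTCTCTCTCTAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r15_pass_u1c
AAAACGTTTCTCTCTCTCTCTCTC
+
IIIIIIIIIIIIIIIIIIIIIIII
@r16_pass_u1c
AAAACGTTTTCCTCCTCCTCCTCC
+
IIIIIIIIIIIIIIIIIIIIIIII
@r17_pass_u1c
AAAACGTTTTTCTTCTTCTTCTTCTTCTTCTTCTAGATCG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r18_pass_u1c
AAAACGTTTCCTTCTCCTTCTCCTTCTCCTTCTCAGATCGGA
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r19_pass_u70k
AAACATGTTTCTCTCTCTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r20_pass_u70k
AAACATGTTTCTCTCTCTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r21_pass_u70k
AAACATGTTTCTCTCTCTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r22_pass_u70k
AAACATGTTTCTCTCTCTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r23_pass_u70k
AAACATGTTTCTCTCTCTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r24_pass_u70k
AAACATGTTTCTCTCTCTCTCTCTCTCAGATCGGAAGAGCGGTTCAG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
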