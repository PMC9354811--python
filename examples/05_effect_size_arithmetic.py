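"""Effect-size arithmetic: partial eta squared and Cohen's d intervals.

These are the closed-form quantities an EMG study reports next to each
F statistic and pairwise contrast: eta_p^2 = F*df1/(F*df1 + df2), and the
z-based 95% CI for d with SE = sqrt((n1+n2)/(n1*n2) + d^2/(2*(n1+n2))).
"""

import emgpress as e

print("partial eta squared at df = (1, 7):")
for f in (9.950, 21.529, 97.288):
    print(f"  F = {f:7.3f}  ->  eta_p^2 = {e.partial_eta_squared(f, 1, 7):.3f}")

print()
print("95% CI for Cohen's d, 8 participants per condition:")
for d in (1.42, 3.68, 9.00):
    lo, hi = e.cohens_d_ci(d, 8, 8)
    print(f"  d = {d:5.2f}  ->  ({lo:.2f}, {hi:.2f})  [{e.hopkins_classify(d)}]")

print()
print("With only 8 subjects, even very large effects carry wide intervals;")
print("the Hopkins label classifies the point estimate, not the interval.")
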