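"""System Usability Scale scoring for a small synthetic evaluation panel.

Scores five synthetic respondents (ratings invented for illustration) with
the standard instrument formula — odd items contribute rating-1, even items
5-rating, sum times 2.5 — and summarizes the panel against the conventional
benchmarks (68 = above average, 80 = top decile).
"""

from lbp_cds import SusResponse, sus_score, sus_summary

panel = [
    SusResponse("u1", (5, 1, 5, 2, 4, 1, 5, 1, 5, 2)),
    SusResponse("u2", (4, 2, 4, 2, 4, 2, 4, 2, 4, 2)),
    SusResponse("u3", (5, 1, 4, 1, 5, 2, 5, 1, 4, 1)),
    SusResponse("u4", (3, 2, 4, 3, 4, 2, 3, 2, 4, 3)),
    SusResponse("u5", (5, 2, 5, 1, 4, 1, 5, 2, 5, 1)),
]
for r in panel:
    print(f"{r.respondent}: SUS = {sus_score(r)}")
s = sus_summary(panel)
print(f"\nn={s.n}  mean={s.mean}  range {s.min}-{s.max}")
print(f"above 68 (above average): {s.percent_above(68):.0f}%")
print(f"above 80 (top decile):    {s.percent_above(80):.0f}%")
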