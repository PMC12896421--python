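"""Classify individual patients with the three-step cutoff algorithm.

For most Child-Pugh A patients the ALBI grade can be read off the
albumin/bilirubin cutoffs directly; only the two mixed zones need the
formula.  The printout shows, per patient, the zone, the grade, and
whether the formula was actually required.
"""

from albigrid import LabPair, albi_score, three_step_classify

patients = [
    ("high albumin", 4.8, 0.5),
    ("low albumin", 3.3, 0.8),
    ("high bilirubin", 3.9, 2.6),
    ("refined favorable", 4.2, 0.7),
    ("refined unfavorable", 3.8, 1.4),
    ("mixed zone, formula", 3.9, 0.5),
    ("mixed zone, formula", 4.2, 1.8),
]

print(f"{'case':<22}{'alb':>5}{'bili':>6}  {'zone':<14}{'grade':>5}  formula?")
for name, alb, bili in patients:
    pair = LabPair(alb, bili)
    res = three_step_classify(pair)
    score = f" (score {albi_score(pair):.2f})" if res.used_formula else ""
    print(f"{name:<22}{alb:>5}{bili:>6}  {res.zone.label:<14}{res.grade:>5}"
          f"  {res.used_formula}{score}")
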