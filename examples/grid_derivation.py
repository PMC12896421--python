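"""Derive the simplified ALBI cutoff zones by exhaustive enumeration.

Every albumin/bilirubin pair reportable at 0.1 precision inside the
Child-Pugh A range is scored with the ALBI formula; the seven-zone
partition then summarises where each grade lives.
"""

from albigrid import GridSpec, render_matrix, run_simulation

summary = run_simulation()
print(f"lattice pairs: {summary.n_total_pairs} "
      f"(CP-B combination box excluded: {summary.n_excluded_cpb})")
print(f"eligible: {summary.n_eligible}  "
      f"formula grade 1: {summary.n_grade1}  grade 2: {summary.n_grade2}")
print(f"directly classifiable by cutoffs alone: "
      f"{summary.n_directly_classifiable} "
      f"({100 * summary.fraction_directly_classifiable:.1f}%)")
for zone, count in sorted(summary.zone_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {zone.label:<14} {count:>4}  ({100 * count / summary.n_eligible:.1f}%)")

# robustness: a coarser 0.2-unit lattice tells the same story
coarse = run_simulation(GridSpec(step=0.2))
print(f"\n0.2-step sensitivity: {coarse.n_directly_classifiable}/"
      f"{coarse.n_eligible} directly classifiable "
      f"({100 * coarse.fraction_directly_classifiable:.1f}%)")

print("\nzone matrix (albumin down, bilirubin across):")
print(render_matrix(summary))
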