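"""Fit discriminant functions and validate them by leave-one-out.

Fits the univariate maxh function and a stepwise-selected multivariate
function on a synthetic cohort, reporting unstandardized coefficients
(within-group score variance 1, sectioning point 0) and the original (O)
versus leave-one-out cross-validated (C) classification rates.
"""

from patellasex import fit_lda, generate_cohort, loocv, pooled_spec, stepwise_select

table = generate_cohort(pooled_spec(seed=1))

fn = fit_lda(table, ("maxh",))
rep_o, rep_c = loocv(table, ("maxh",))
print("Univariate maxh function: y = "
      f"{fn.coefficients[0]:.3f}·maxh {fn.constant:+.3f}  (y > 0 → male)")
print(f"  O: {rep_o.average_pct:.1f}%  (M {rep_o.male_pct:.1f}, F {rep_o.female_pct:.1f})")
print(f"  C: {rep_c.average_pct:.1f}%  (M {rep_c.male_pct:.1f}, F {rep_c.female_pct:.1f})")

trace = stepwise_select(table)
print(f"\nStepwise selection (Wilks' Λ, F-enter 3.84 / F-remove 2.71): "
      f"{trace.entered}")
fn2 = fit_lda(table, tuple(trace.entered))
terms = " + ".join(
    f"{c:.3f}·{v}" for v, c in zip(fn2.variables, fn2.coefficients)
)
print(f"  y = {terms} {fn2.constant:+.3f}")
rep_o2, rep_c2 = loocv(table, tuple(trace.entered))
print(f"  O: {rep_o2.average_pct:.1f}%   C: {rep_c2.average_pct:.1f}% "
      "(a small O→C drop indicates a stable, non-overfit function)")
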