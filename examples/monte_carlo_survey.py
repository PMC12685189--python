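"""Scaled-down Monte Carlo stability survey across the four growth conditions.

Draws random parameter sets and initial conditions (log-uniform for most
quantities, uniform for D, Q, mu), integrates each for 20,000 time units,
and tabulates outcome categories.  The full study used millions of draws per
condition; a few hundred per condition reproduce the qualitative picture:
stability is common for cooperators with a biofilm, rarer with cheaters,
and impossible with cheaters but no biofilm.
"""

from biofilmchemostat import CONDITIONS, default_design, run_monte_carlo

N = 300
for condition in CONDITIONS:
    table = run_monte_carlo(default_design(condition), N, seed=100)
    fr = table.category_fractions()
    frs = "  ".join(f"{k.split('_')[0]}={v:.1%}" for k, v in fr.items() if v)
    print(f"{condition:26s} n={N}  {frs}")
print()
print("'full' = every enabled variant ends above 0.01 concentration with")
print(">= 5% of the population; 'tragedy' = all variants below 0.01.")
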