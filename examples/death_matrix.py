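"""The cohort death matrix and its stationary symmetries.

Project every living cohort to extinction under the period life table.  Row
a is the death band of the cohort now aged a (it sums to the cohort size);
column y counts persons with y completed years remaining.  For a stationary
population rows equal columns age-for-age and every anti-diagonal is
constant; an observed (here: growing) population breaks both.
"""

from demopair import (
    GompertzMakeham,
    StableStructure,
    build_death_matrix,
    cohort_death_band,
    make_life_table,
    make_pair,
    make_stable_population,
    matrix_checksums,
    thanatological_bar,
)

lt = make_life_table(GompertzMakeham(makeham=1e-3, gompertz_a=5e-5, gompertz_b=0.09))
observed = make_stable_population(StableStructure(0.015, lt), total=1_000_000, time=2020)
pair = make_pair(observed)

for name, pop in [("observed", pair.observed), ("stationary", pair.stationary)]:
    dm = build_death_matrix(pop)
    chk = matrix_checksums(dm)
    band_total = sum(v for _, v in cohort_death_band(dm, 50))
    bar = thanatological_bar(dm, 50)
    print(f"{name:>10}: cohort aged 50 = {pop.n[50]:>9.0f}  projected band deaths = {band_total:>9.0f}")
    print(f"{'':>10}  persons with exactly 50y left = {bar.column_total:>9.0f}, at least 50y = {bar.tail:>9.0f}")
    print(f"{'':>10}  rows=columns: {chk['rows_equal_columns']}, anti-diagonals constant: {chk['anti_diagonals_constant']}")
print()
print("Each band total equals its cohort (deaths are conserved). Only the")
print("stationary member satisfies the row/column and anti-diagonal identities.")
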