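#!/usr/bin/env python
"""Shell morphometrics: filtering, population aggregation and group tests.

Reads the simulated shell table, applies the 5-cm ontogenetic filter,
aggregates to population means, and runs the population-level comparisons:
normality of the index distribution, viable-vs-declining t-test, the
width-on-length ANCOVA, the latitude x period separate-slopes model and the
latitude/altitude rank correlations. Writes ``results/populations.csv`` and
``results/morphometry_tests.csv``.
"""

from pathlib import Path

import pandas as pd

from pearlclim import io as io_mod
from pearlclim import morphometry as m

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records, status_map = io_mod.read_shells_csv(ROOT / "world" / "shells.csv")
    kept = m.filter_shells(records)
    print(f"5-cm filter: kept {len(kept)}/{len(records)} shells")

    by_pop: dict[str, list] = {}
    for r in kept:
        by_pop.setdefault(r.population_id, []).append(r)
    populations = [
        m.aggregate_population(recs, status=status_map.get(pid, "unknown"))
        for pid, recs in sorted(by_pop.items())
    ]
    io_mod.write_populations_csv(populations, ROOT / "populations.csv")

    viable = [p for p in populations if p.status == "viable"]
    declining = [p for p in populations if p.status == "declining"]
    historical = [p for p in populations if p.period == "historical"]
    rows = []

    norm = m.normality_check([p.mean_sci for p in populations])
    rows.append({"test": "lilliefors_mean_sci", "statistic": norm.statistic,
                 "p": norm.p, "n": norm.n})
    print(f"normality of population mean SCI: D={norm.statistic:.3f} "
          f"p={norm.p:.3f} ({'normal' if norm.p > 0.05 else 'non-normal'})")

    t = m.compare_group_means(viable, declining)
    rows.append({"test": "t_viable_vs_declining", "statistic": t.t_stat,
                 "p": t.p, "n": t.df + 2})
    print(f"viable ({len(viable)}) vs declining ({len(declining)}): "
          f"t={t.t_stat:.2f}, df={t.df}, p={t.p:.2g}")

    glm = m.fit_width_glm(viable + declining)
    rows.append({"test": "width_glm_retained:" + "+".join(glm.retained_terms),
                 "statistic": glm.r_squared, "p": float("nan"),
                 "n": len(viable) + len(declining)})
    print(f"width ANCOVA (viable vs declining): retained {glm.retained_terms}, "
          f"R^2={glm.r_squared:.3f}")

    lowland, _ = m.split_by_altitude(populations)
    ss = m.separate_slopes_test(lowland)
    rows.append({"test": "separate_slopes_latitude_period",
                 "statistic": ss.f_stat, "p": ss.p, "n": len(lowland)})
    print(f"separate slopes (lowland, latitude x period): F={ss.f_stat:.1f}, "
          f"df={ss.df_num}, p={ss.p:.2g}")

    recent_lowland = [p for p in lowland if p.period == "recent"]
    rho = m.rank_correlation([p.latitude_deg for p in recent_lowland],
                             [p.mean_sci for p in recent_lowland])
    rows.append({"test": "spearman_latitude_sci_recent", "statistic": rho.statistic,
                 "p": rho.p, "n": rho.n})
    print(f"recent lowland latitude vs SCI: rho={rho.statistic:.2f}, "
          f"n={rho.n}, p={rho.p:.2g}")

    bias = m.rank_correlation([p.n_shells for p in populations],
                              [p.mean_sci for p in populations])
    rows.append({"test": "spearman_sample_size_sci", "statistic": bias.statistic,
                 "p": bias.p, "n": bias.n})
    print(f"sample-size bias check: rho={bias.statistic:.2f}, p={bias.p:.2f}")

    pd.DataFrame(rows).to_csv(ROOT / "morphometry_tests.csv", index=False)
    print(f"wrote {ROOT / 'morphometry_tests.csv'}")


if __name__ == "__main__":
    main()
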