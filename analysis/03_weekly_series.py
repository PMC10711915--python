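"""Build the weekly per-household series for every category and measure.

Applies the household filter (fewer than six weekly purchases excluded), then
reduces purchase events to weighted weekly means — volume (mL, or g for
powders and confectionery) and sugar mass (g) — and writes one series file per
category x measure under results/series/.
"""

from common import PANEL_DIR, RESULTS

from sdil import aggregate
from sdil.study import SUGARLESS_CATEGORIES, StudyConfig, StudyInputs


def main() -> None:
    inputs = StudyInputs.from_dir(PANEL_DIR)
    retained, excluded = aggregate.filter_households(inputs.events, min_weekly_purchases=6)
    print(f"household filter: {len(excluded)} household-weeks excluded, "
          f"{len(retained):,} events retained")

    out = RESULTS / "series"
    out.mkdir(parents=True, exist_ok=True)
    categories = sorted(set(inputs.category_map.values))
    n_written = 0
    for label in categories:
        for measure in ("volume", "sugar_mass"):
            if measure == "sugar_mass" and label in SUGARLESS_CATEGORIES:
                continue
            series = aggregate.weekly_weighted_mean(
                retained, inputs.category_map, inputs.weights, label, measure,
                sugar_concentration=inputs.sugar_concentration,
            )
            series.write(out / f"{label}_{measure}.csv")
            n_written += 1
            pre = series.values[:107]
            print(f"  {label:22s} {measure:10s} preannouncement mean "
                  f"{pre.mean():8.1f} {series.unit}")
    print(f"wrote {n_written} series files to {out}")


if __name__ == "__main__":
    main()
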