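"""Generate the demonstration purchase panel.

Simulates the default synthetic study conditions — eleven levy-relevant
categories over 266 weeks spanning the levy's announcement (week 107) and
implementation (week 214) — and writes purchases/products/weights CSVs plus a
ground-truth sidecar under results/panel/.
"""

from common import N_HOUSEHOLDS, PANEL_DIR, SEED

from sdil import synthetic


def main() -> None:
    cfg = synthetic.default_config(n_households=N_HOUSEHOLDS, seed=SEED)
    catalogue = synthetic.simulate_catalogue(cfg)
    events, weights, truth = synthetic.simulate_panel(cfg, catalogue)
    synthetic.write_panel(PANEL_DIR, events, catalogue, weights, truth)
    cal = cfg.calendar
    print(f"panel: {cfg.n_households} households x {cal.n_weeks} weeks "
          f"({cal.start_date} onward), {len(events):,} purchase events")
    print(f"announcement week {cal.announcement_week}, implementation week {cal.implementation_week}")
    print(f"wrote {PANEL_DIR}/purchases.csv, products.csv, weights.csv, ground_truth.json")


if __name__ == "__main__":
    main()
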