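"""Assign levy categories to the catalogue and flag small manufacturers.

Writes the product -> category map and, for the two exclusion thresholds,
the small-manufacturer flags. The published thresholds (1M and 0.5M litres of
levy-liable volume per year) refer to volumes observed in the full ~22k
household panel, so they are scaled here by the demonstration panel's size.
"""

import pandas as pd

from common import FULL_PANEL_HOUSEHOLDS, N_HOUSEHOLDS, PANEL_DIR, RESULTS

from sdil import classify


def main() -> None:
    products = classify.read_products(PANEL_DIR / "products.csv")
    purchases = pd.read_csv(PANEL_DIR / "purchases.csv")
    labels = classify.classify_catalogue(products)
    classify.write_category_map(labels, RESULTS / "category_map.csv")
    print(f"classified {len(labels)} products into {labels.nunique()} categories:")
    print(labels.value_counts().to_string())

    scale = N_HOUSEHOLDS / FULL_PANEL_HOUSEHOLDS
    for litres in (1_000_000.0, 500_000.0):
        flags = classify.small_manufacturer_flags(purchases, products, litres * scale)
        flags.to_csv(RESULTS / f"small_manufacturers_{litres:.0f}L.csv")
        print(f"\nthreshold {litres:,.0f} L/yr (panel-scaled {litres * scale:,.0f} L): "
              f"{int(flags.sum())} of {len(flags)} manufacturers flagged small")


if __name__ == "__main__":
    main()
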