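#!/usr/bin/env python
"""Plot sweep CSVs produced by the metaecosim CLI (optional helper).

Consumes only the tidy CSV outputs; the library itself never plots.

Usage:
    python scripts/plot_sweeps.py state_diagram.csv -o diagram.png
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

STATE_COLORS = {
    "HOM_EQ": "#b0b0b0",
    "HOM_OSC": "#ffffff",
    "HET_OSC": "#dce9f5",
    "HET_EQ": "#3b76af",
    "MIXED": "#f5e0a0",
    "FAILED": "#d62728",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("csv", type=Path)
    ap.add_argument("-o", "--out", type=Path, default=Path("sweep.png"))
    args = ap.parse_args()

    df = pd.read_csv(args.csv)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if {"d_CA", "d_CB"} <= set(df.columns):
        x, y = "d_CA", "d_CB"
    else:
        x, y = "d_N", "d_C"
    for code, sub in df.groupby("state_code"):
        ax.scatter(
            sub[x], sub[y], c=STATE_COLORS.get(code, "k"),
            label=code, marker="s", s=60, edgecolors="0.6", linewidths=0.3,
        )
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(fontsize=8, loc="upper left", framealpha=0.9)
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
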