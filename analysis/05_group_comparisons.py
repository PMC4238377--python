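#!/usr/bin/env python
"""Between-strain comparisons on the simulated cohort.

Welch t test on soma diameters (GCL melanopsin cells, pigmented vs albino)
and Mann-Whitney tests on per-retina hemiretinal shares; significance at
p < 0.05.  Writes results/stats/group_comparisons.json.
"""

import argparse
import json
from pathlib import Path

from retinotopo.geometry import canonicalize
from retinotopo.io import load_table
from retinotopo.pipeline import AnalysisConfig, analyze


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("scratch/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/stats"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    tables, names = [], []
    for stem in sorted(args.datadir.glob("*_*.geometry.json")):
        base = stem.with_suffix("").with_suffix("")
        tables.append(load_table(f"{base}.cells.csv", stem))
        names.append(base.name)
    summary = analyze(tables, AnalysisConfig(), names=names)
    gs = summary.get("group_stats", {})
    (args.outdir / "group_comparisons.json").write_text(json.dumps(gs, indent=2) + "\n")

    if "soma_diameter_t_test" in gs:
        t = gs["soma_diameter_t_test"]
        print(f"soma diameter {gs['order'][0]} vs {gs['order'][1]}: "
              f"t = {t['statistic']:.2f}, p = {t['p_value']:.2e} "
              f"({'significant' if t['significant'] else 'n.s.'}; "
              f"n = {t['n'][0]}/{t['n'][1]})")
    for key in ("temporal_share_mann_whitney", "superior_share_mann_whitney"):
        if key in gs:
            m = gs[key]
            print(f"{key}: U = {m['statistic']:.1f}, p = {m['p_value']:.3f} "
                  f"({'significant' if m['significant'] else 'n.s.'})")
    print(f"\nresults under {args.outdir}")


if __name__ == "__main__":
    main()
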