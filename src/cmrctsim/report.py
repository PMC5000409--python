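"""Figures and summary text from a grid result table.

Mirrors the usual presentation of non-compliance simulation studies: per
scenario family (one correlation sign, one model) a bias panel and a power
panel, refusal level on the x axis, one series per analysis method and one
subplot column per correlation tier; the power panel carries a reference
line at the design power.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["render_report"]

_METHOD_ORDER = ["itt", "pp", "2sps", "2sri"]
_TIER_ORDER = ["zero", "low", "medium", "high"]


def render_report(results: pd.DataFrame, outdir: str | Path,
                  target_power: float = 0.8) -> list[Path]:
    """Write bias/power figure pairs and a text summary; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if results.empty:
        warnings.warn("empty results table: nothing to report")
        (outdir / "summary.txt").write_text("no results\n")
        return [outdir / "summary.txt"]

    for (model, sign), fam in results.groupby(["model", "sign_p"]):
        tiers = [t for t in _TIER_ORDER if t in set(fam["tier_p"])]
        fig, axes = plt.subplots(2, max(len(tiers), 1), squeeze=False,
                                 figsize=(3.2 * max(len(tiers), 1), 6.4),
                                 sharex=True, sharey="row")
        for col, tier in enumerate(tiers):
            sub = fam[fam["tier_p"] == tier]
            for method in [m for m in _METHOD_ORDER if m in set(sub["method"])]:
                ms = sub[sub["method"] == method].sort_values("p")
                axes[0][col].plot(ms["p"], ms["pct_bias"], marker="o", label=method)
                axes[1][col].plot(ms["p"], ms["power"], marker="o", label=method)
            axes[0][col].axhline(0.0, color="grey", lw=0.8)
            axes[1][col].axhline(target_power, color="black", lw=1.2)
            axes[0][col].set_title(f"tier {tier}")
            axes[1][col].set_xlabel("mean refusal probability p")
        axes[0][0].set_ylabel("percentage bias of $\\hat\\beta$")
        axes[1][0].set_ylabel("empirical power")
        axes[0][0].legend(fontsize=8)
        fig.suptitle(f"model: {model}, refusal-risk correlation sign: {sign}")
        fig.tight_layout()
        path = outdir / f"panels_{model}_{sign}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    lines = ["scenario summaries (percentage bias [95% CI], power):"]
    for _, r in results.iterrows():
        lines.append(
            f"  {r['label']:<45s} {r['method']:>5s}: bias {r['pct_bias']:+6.1f}% "
            f"[{r['pct_bias_lo']:+.1f}, {r['pct_bias_hi']:+.1f}], power {r['power']:.3f}"
        )
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
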