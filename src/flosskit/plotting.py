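"""Optional matplotlib figures mirroring the group-comparison layout."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_comparison(comp: dict, path: str | Path, title: str = "") -> None:
    """One panel per sex: conditional survival curves for both groups."""
    sexes = [k for k in ("F", "M") if comp.get(k)]
    fig, axes = plt.subplots(1, max(len(sexes), 1), figsize=(5 * len(sexes), 4),
                             squeeze=False)
    for ax, sex in zip(axes[0], sexes):
        res = comp[sex]
        for grp, stats in res["groups"].items():
            curve = stats["curve"]
            ax.step(curve.ages, curve.survival, where="post", label=grp)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("conditional survival")
        ax.set_title(f"{title} — {'females' if sex == 'F' else 'males'}")
        ax.set_ylim(0, 1.02)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
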