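"""Optional figure output: Kaplan-Meier curves per risk group and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_COLORS = {"low": "tab:green", "moderate": "tab:orange", "high": "tab:red"}


def km_plot(report, path: str | Path) -> None:
    kinds = list(report.scores)
    fig, axes = plt.subplots(1, len(kinds), figsize=(5 * len(kinds), 4), squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        for cat, curve in report.scores[kind]["km"].items():
            xs = [0.0] + list(curve["times"])
            ys = [1.0] + list(curve["survival"])
            ax.step(xs, ys, where="post", label=f"{cat} (n={curve['n']})",
                    color=_COLORS.get(cat))
        ax.set_xlabel("years since score calculation")
        ax.set_ylabel("peri-implantitis-free survival")
        ax.set_ylim(0, 1.02)
        ax.set_title(kind)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(report, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for kind, section in report.scores.items():
        roc = section.get("roc")
        if roc is None:
            continue
        ax.plot(roc["fpr"], roc["tpr"], marker="o", label=f"{kind} (AUC={roc['auc']:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
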