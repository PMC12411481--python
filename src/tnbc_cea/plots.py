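"""Matplotlib figures for the sensitivity analyses (tornado, CE plane, CEAC)."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # file output only
import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import CEACPoint, PSAResult, TornadoEntry

__all__ = ["tornado_plot", "ce_plane_plot", "ceac_plot"]


def tornado_plot(entries: Sequence[TornadoEntry], base_icer: float,
                 path=None, max_bars: int = 12):
    shown = [e for e in entries if np.isfinite(e.width)][:max_bars][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.icer_lower, e.icer_upper))
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def ce_plane_plot(psa: PSAResult, wtp: float, path=None):
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=6, alpha=0.4, color="#4878a8")
    q = np.linspace(*ax.get_xlim(), 50)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def ceac_plot(points: Sequence[CEACPoint], wtp: Optional[float] = None, path=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.probability for p in points], color="#4878a8")
    if wtp is not None:
        ax.axvline(wtp, color="k", lw=1, ls="--", label=f"WTP ${wtp:,.0f}/QALY")
        ax.legend(fontsize=8)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
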