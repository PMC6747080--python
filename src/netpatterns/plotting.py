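"""Matplotlib plots of K-curves against their CSR envelopes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kfunction import KEnvelope, KResult

__all__ = ["plot_k_envelope"]


def plot_k_envelope(
    observed: KResult, env: KEnvelope, path, title: str | None = None
) -> None:
    """Observed K(t) with the Monte Carlo CSR envelope band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(env.t_grid, env.lower, env.upper, color="0.85",
                    label=f"CSR envelope ({env.alpha:.0%} pointwise)")
    ax.plot(env.t_grid, env.mean, "--", color="0.4", label="Exp (mean)")
    ax.plot(observed.t_grid, observed.k, color="tab:blue", label="obs")
    ax.set_xlabel("network distance t (m)")
    ax.set_ylabel("K(t)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
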