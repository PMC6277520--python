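"""Figure helpers: mirrored radial profiles and per-cell MDP dot plots."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .radial import mirror_profile  # noqa: E402
from .types import PopulationProfile, RadialProfile  # noqa: E402


def plot_mirrored_profile(profile: RadialProfile, path, label: str = ""):
    """Single-cell radial profile mirrored about r = 0."""
    bins, values = mirror_profile(profile)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(bins, values, "k.-", lw=1)
    ax.set_xlabel("radius (pixels)")
    ax.set_ylabel("absorbance (a.u.)")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_population_comparison(pre: PopulationProfile, post: PopulationProfile,
                               path, labels=("before", "after")):
    """Mean ± SEM population profiles of two arms, mirrored about r = 0."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for pop, color, label in ((pre, "black", labels[0]),
                              (post, "gray", labels[1])):
        ok = np.isfinite(pop.mean)
        b = pop.bins[ok]
        m = pop.mean[ok]
        s = pop.sem[ok]
        bins = np.concatenate([-b[:0:-1], b])
        mean = np.concatenate([m[:0:-1], m])
        sem = np.concatenate([s[:0:-1], s])
        ax.errorbar(bins, mean, yerr=sem, color=color, label=label,
                    lw=1, capsize=2)
    ax.set_xlabel("radius (pixels)")
    ax.set_ylabel("absorbance (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mdp_dotplot(records, path, value: str = "mdp_mv"):
    """One jittered dot per cell, grouped by condition."""
    conditions = sorted(records["condition"].unique())
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(1.2 * len(conditions) + 1.5, 3.2))
    for i, cond in enumerate(conditions):
        vals = records.loc[records["condition"] == cond, value].to_numpy()
        x = i + rng.uniform(-0.15, 0.15, len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="black", lw=1.5)
    ax.set_xticks(range(len(conditions)), conditions, rotation=30, ha="right")
    ax.set_ylabel("MDP (mV)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
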