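"""Silhouette visualisation: per-patient lesion-similarity scatter."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .similarity import SilhouetteResult


def plot_patient_silhouettes(result: SilhouetteResult,
                             patient_of: dict | None = None,
                             path: str | Path | None = None,
                             seed: int = 0):
    """Scatter of per-lesion silhouette values by (anonymised) patient index.

    ``patient_of`` maps lesion id to patient id; when omitted, lesion ids of
    the form ``<patient>_<lesion>`` are parsed.  Patients are shuffled and
    assigned arbitrary indices and colors, so the plot carries no
    identifying order.  Returns the matplotlib figure; saves it when
    ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if patient_of is None:
        patient_of = {lid: str(lid).rsplit("_", 1)[0]
                      for lid in result.per_lesion.index}
    rng = np.random.default_rng(seed)
    pids = [p for p in result.per_patient.index
            if not result.per_patient.loc[p, "excluded"]]
    order = rng.permutation(len(pids))
    index_of = {p: int(order[i]) + 1 for i, p in enumerate(pids)}
    colors = rng.random((len(pids), 3)) * 0.8

    fig, ax = plt.subplots(figsize=(8, 4))
    for i, p in enumerate(pids):
        vals = [v for lid, v in result.per_lesion.items()
                if patient_of.get(lid) == p]
        if not vals:
            continue
        ax.scatter([index_of[p]] * len(vals), vals, s=12, color=colors[i])
    ax.axhline(0.0, color="grey", lw=0.8)
    if not np.isnan(result.mean_index):
        ax.axhline(result.mean_index, color="red", lw=0.8, ls="--",
                   label=f"cohort mean {result.mean_index:.3f}")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("patient (random index)")
    ax.set_ylabel("silhouette")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title(f"Intra-patient lesion similarity — {result.slicing}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
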