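"""Assessment graphics, PCoA ordination and state-sequence diagrams."""

from __future__ import annotations

import numpy as np

from .beta_diversity import DistanceMatrix

__all__ = ["plot_assessment", "pcoa", "plot_ordination", "plot_state_sequence"]

_METRIC_COLORS = {
    "jsd": "#1f77b4",
    "rjsd": "#ff7f0e",
    "braycurtis": "#2ca02c",
    "morisitahorn": "#d62728",
    "kulczynski": "#9467bd",
}


def _use_agg():
    import matplotlib

    matplotlib.use("Agg", force=False)


def plot_assessment(records, config, algorithm_id: str = "pam"):
    """Three-panel SI / PS / Jaccard vs k figure, one line per metric.

    Dashed horizontal lines mark the configured thresholds (plus the 0.50
    "strong clusters" reference on the silhouette panel).  Combinations with
    missing scores gap the line.
    """
    _use_agg()
    import matplotlib.pyplot as plt

    recs = [r for r in records if r.algorithm_id == algorithm_id]
    if not recs:
        raise ValueError(f"no records for algorithm {algorithm_id!r}")
    metrics = [m for m in _METRIC_COLORS if any(r.metric_id == m for r in recs)]
    extra = sorted({r.metric_id for r in recs} - set(metrics))
    metrics += extra

    panels = [
        ("SI", lambda r: r.si, [config.si_threshold, 0.50]),
        ("PS", lambda r: r.ps_mean, [config.ps_threshold]),
        ("Jaccard", lambda r: r.jaccard_mean, [config.jaccard_threshold]),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
    for ax, (title, getter, thresholds) in zip(axes, panels):
        for m in metrics:
            pts = sorted(((r.k, getter(r)) for r in recs if r.metric_id == m),
                         key=lambda p: p[0])
            ks = [p[0] for p in pts]
            ys = [np.nan if p[1] is None else p[1] for p in pts]
            if ks:
                ax.plot(ks, ys, marker="o", ms=3, label=m,
                        color=_METRIC_COLORS.get(m))
        for t in thresholds:
            ax.axhline(t, ls="--", lw=0.8, color="grey")
        ax.set_title(title)
        ax.set_xlabel("k")
        ax.set_ylim(-0.05 if title == "SI" else 0.0, 1.05)
    axes[0].set_ylabel("score")
    axes[-1].legend(fontsize=7, loc="lower right")
    fig.suptitle(f"Clustering assessment ({algorithm_id})")
    fig.tight_layout()
    return fig


def pcoa(D, dims: int = 2) -> np.ndarray:
    """Classical-scaling coordinates of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top ``dims`` positive-eigenvalue axes scaled by the square root of their
    eigenvalues.  Axis signs are fixed by making each axis's
    largest-magnitude loading positive.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d * d) @ j
    b = 0.5 * (b + b.T)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12
    coords = np.zeros((n, dims))
    m = min(dims, int(positive.sum()))
    if m:
        coords[:, :m] = eigvec[:, :m] * np.sqrt(eigval[:m])
    for a in range(m):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    return coords


def plot_ordination(D, labels=None, title: str = "PCoA"):
    """2-D principal-coordinates scatter, colored by state labels."""
    _use_agg()
    import matplotlib.pyplot as plt

    coords = pcoa(D, dims=2)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=14)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            mask = labels == lab
            ax.scatter(coords[mask, 0], coords[mask, 1], s=14,
                       label=f"state {lab}")
        ax.legend(fontsize=7)
    ax.set_xlabel("PCo1")
    ax.set_ylabel("PCo2")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_state_sequence(states, metadata: dict[str, dict]):
    """Subjects x time grid colored by state; grey cells mark missing samples.

    ``states`` must be a selected :class:`RobustStates` (it supplies
    ``sample_ids`` and ``labels``); ``metadata`` supplies ``subject_id`` and
    ``time_index`` per sample.
    """
    _use_agg()
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from matplotlib.patches import Patch

    if getattr(states, "outcome", "selected") == "none":
        raise ValueError("no robust states selected; nothing to draw")
    pairs = {}
    for sid, lab in zip(states.sample_ids, states.labels):
        meta = metadata.get(sid, {})
        subj, t = meta.get("subject_id"), meta.get("time_index")
        if subj is None or t is None:
            continue
        pairs[(str(subj), int(t))] = int(lab)
    if not pairs:
        raise ValueError(
            "metadata carries no subject_id/time_index; use the static "
            "(ordination) report instead")
    subjects = sorted({s for s, _ in pairs})
    times = sorted({t for _, t in pairs})
    grid = np.full((len(subjects), len(times)), np.nan)
    for (subj, t), lab in pairs.items():
        grid[subjects.index(subj), times.index(t)] = lab

    k = int(np.nanmax(grid))
    cmap = colormaps["tab10"].resampled(max(k, 1))
    cmap = cmap.copy()
    cmap.set_bad("#bbbbbb")  # grey: no sample at that time point
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(times)), max(2, 0.35 * len(subjects))))
    ax.imshow(np.ma.masked_invalid(grid), cmap=cmap, aspect="auto",
              interpolation="nearest", vmin=0.5, vmax=max(k, 1) + 0.5)
    ax.set_yticks(range(len(subjects)), subjects, fontsize=7)
    ax.set_xticks(range(len(times)), times, fontsize=7)
    ax.set_xlabel("time point")
    ax.set_ylabel("subject")
    handles = [Patch(color=cmap((c - 0.5) / max(k, 1)), label=f"state {c}")
               for c in range(1, k + 1)]
    handles.append(Patch(color="#bbbbbb", label="missing"))
    ax.legend(handles=handles, fontsize=6, bbox_to_anchor=(1.02, 1),
              loc="upper left")
    fig.tight_layout()
    return fig
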