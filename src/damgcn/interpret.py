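"""Attention-based interpretability: band-weight trajectories and
degree-centrality electrode importance maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from damgcn.model import DAMGCNModel
from damgcn.montage import Montage

__all__ = [
    "AttentionReport",
    "band_weight_trajectory",
    "band_weights_from_attention",
    "degree_centrality",
    "channel_importance",
    "topomap_export",
]


@dataclass
class AttentionReport:
    """Per-band proportions over training plus per-channel centralities."""

    band_proportions: np.ndarray | None  # (epochs, F), each row sums to 1
    channel_centrality: np.ndarray | None  # (C,)
    channel_names: tuple[str, ...] | None = None
    band_names: tuple[str, ...] | None = None
    aggregation: dict | None = None


def band_weight_trajectory(checkpoints) -> np.ndarray:
    """Per-epoch softmax band-gate proportions, ordered by epoch.

    ``checkpoints`` is a sequence of trained models, of raw gate vectors, or
    a (epochs, F) gate-history array recorded during training.
    """
    rows = []
    arr = np.asarray(checkpoints) if not isinstance(checkpoints, (list, tuple)) else None
    if arr is not None and arr.ndim == 2:
        return np.asarray([_assert_simplex(r) for r in arr])
    for ckpt in checkpoints:
        if isinstance(ckpt, DAMGCNModel):
            rows.append(ckpt.band_gate_proportions())
        else:
            g = np.asarray(ckpt, dtype=float)
            e = np.exp(g - g.max())
            rows.append(e / e.sum())
    if not rows:
        raise ValueError("no checkpoints supplied")
    return np.asarray(rows)


def _assert_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("gate history rows must already be simplex proportions")
    return p


def degree_centrality(attention: np.ndarray, mode: str = "symmetric") -> np.ndarray:
    """Node importance ``DC_i = k_i / (N - 1)`` from an attention matrix.

    ``k_i`` sums node i's connection weights to all *other* nodes.  Because
    attention matrices are row-stochastic but not symmetric, the default
    symmetrizes with ``(A + A^T) / 2`` before summing; ``mode='out'`` /
    ``mode='in'`` use raw row / column sums instead.
    """
    a = np.asarray(attention, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"attention must be square, got {a.shape}")
    if np.any(a < 0):
        raise ValueError("attention weights must be nonnegative")
    n = a.shape[0]
    if mode == "symmetric":
        a = 0.5 * (a + a.T)
        k = a.sum(axis=1) - np.diag(a)
    elif mode == "out":
        k = a.sum(axis=1) - np.diag(a)
    elif mode == "in":
        k = a.sum(axis=0) - np.diag(a)
    else:
        raise ValueError(f"unknown centrality mode {mode!r}")
    return k / (n - 1)


def channel_importance(
    model: DAMGCNModel,
    features: np.ndarray,
    graph=None,
    mode: str = "symmetric",
    batch_size: int = 256,
) -> AttentionReport:
    """Degree centrality of the channel-attention matrix on evaluation data.

    Attention maps are averaged over heads, encoder layers, and samples
    before the centrality computation.
    """
    if not model.config.use_dam:
        raise ValueError("model has no attention block (use_dam=False)")
    features = np.asarray(features, dtype=float)
    c = model.config.num_channels
    acc = np.zeros((c, c))
    n = 0
    for start in range(0, len(features), batch_size):
        batch = features[start : start + batch_size]
        _, trace = model.forward(batch, graph, training=False)
        # (layers, heads, C, C) already batch-averaged -> weight by batch size
        acc += trace.channel_attention.mean(axis=(0, 1)) * len(batch)
        n += len(batch)
    mean_attention = acc / n
    dc = degree_centrality(mean_attention, mode=mode)
    return AttentionReport(
        band_proportions=None,
        channel_centrality=dc,
        channel_names=None,
        aggregation={
            "heads": model.config.num_heads,
            "layers": model.config.num_encoders,
            "samples": n,
            "mode": mode,
        },
    )


def band_weights_from_attention(model: DAMGCNModel, features: np.ndarray, graph=None) -> np.ndarray:
    """Alternative band-weight extractor: mean attention mass received by
    each band token in the band encoder, normalized to a simplex."""
    if not model.config.use_dam:
        raise ValueError("model has no attention block (use_dam=False)")
    _, trace = model.forward(np.asarray(features, dtype=float), graph, training=False)
    mass = trace.band_attention.mean(axis=(0, 1)).sum(axis=0)  # column mass
    return mass / mass.sum()


def topomap_export(
    report: AttentionReport,
    montage: Montage,
    csv_path=None,
    png_path=None,
) -> "object":
    """Write per-channel centralities as CSV and optionally render a 2-D
    scalp projection (azimuthal equidistant) as PNG.  Returns a DataFrame."""
    import pandas as pd

    if report.channel_centrality is None:
        raise ValueError("report has no channel centralities")
    values = np.asarray(report.channel_centrality, dtype=float)
    names = report.channel_names or montage.channel_names
    if len(values) != montage.n_channels or tuple(names) != tuple(montage.channel_names):
        missing = sorted(set(names or ()) ^ set(montage.channel_names))
        raise ValueError(f"channel name mismatch with montage: {missing}")

    df = pd.DataFrame({"channel": list(names), "centrality": values})
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        xyz = montage.coords / np.linalg.norm(montage.coords, axis=1, keepdims=True)
        theta = np.arccos(np.clip(xyz[:, 2], -1, 1))
        phi = np.arctan2(xyz[:, 1], xyz[:, 0])
        r = theta / (np.pi / 2)  # ear ring at radius 1
        px, py = r * np.cos(phi), r * np.sin(phi)
        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(px, py, c=values, s=220, cmap="viridis")
        for x, y, name in zip(px, py, names):
            ax.annotate(name, (x, y), ha="center", va="center", fontsize=5)
        ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1))
        ax.set_aspect("equal")
        ax.axis("off")
        fig.colorbar(sc, ax=ax, shrink=0.7, label="degree centrality")
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return df
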