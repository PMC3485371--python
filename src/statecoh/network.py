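"""Band-wise task-positive / task-negative network construction.

Takes a bootstrap-ratio (BSR) map over (frequency bin x node-pair), thresholds
it at a percentile of the |BSR| distribution, reduces supra-threshold bins to
one extremal entry per canonical frequency band and node-pair, and summarises
the resulting signed networks by node degree.

Degree counts *distinct neighbour nodes* across the union of all bands'
edges, so a pair connected in both beta and gamma contributes once.  Nodes
reaching a minimum degree are tabulated with the frequency span of their
contributing bands (e.g. beta + gamma edges report "16-64" Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "band_range",
    "validate_bands",
    "assign_band_bins",
    "bsr_threshold",
    "band_reduce",
    "band_supra_counts",
    "node_degree",
    "BandNetwork",
    "build_band_network",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band [f_lo, f_hi) in Hz (top band closes at f_hi)."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi})")


#: Canonical cortical-rhythm partition of the 4-64 Hz analysis range.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 16.0),
    Band("beta", 16.0, 32.0),
    Band("gamma", 32.0, 64.0),
)


def band_range(name: str, bands: Sequence[Band] = DEFAULT_BANDS) -> tuple[float, float]:
    """(f_lo, f_hi) of a named band; raises on unknown names."""
    for b in bands:
        if b.name == name:
            return (b.f_lo, b.f_hi)
    raise ValueError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


def validate_bands(bands: Sequence[Band]) -> None:
    """Bands must be ascending, non-overlapping and contiguous."""
    if not bands:
        raise ValueError("empty band list")
    for a, b in zip(bands, bands[1:]):
        if abs(a.f_hi - b.f_lo) > 1e-9:
            raise ValueError(
                f"bands must be contiguous and ascending: {a.name} ends at "
                f"{a.f_hi} but {b.name} starts at {b.f_lo}"
            )


def assign_band_bins(freqs: np.ndarray, bands: Sequence[Band]) -> np.ndarray:
    """Band name per frequency bin; [f_lo, f_hi), last band closed above.

    Raises if any bin falls outside every band.
    """
    validate_bands(bands)
    freqs = np.asarray(freqs, dtype=float)
    out = np.empty(freqs.shape, dtype=object)
    for band in bands:
        hi_closed = band is bands[-1]
        in_band = (freqs >= band.f_lo) & (
            (freqs <= band.f_hi) if hi_closed else (freqs < band.f_hi)
        )
        out[in_band] = band.name
    if any(v is None for v in out):
        bad = freqs[np.array([v is None for v in out])]
        raise ValueError(f"frequency bins outside every band: {bad}")
    return out


def bsr_threshold(
    bsr: np.ndarray, percentile: float = 99.9, mode: str = "absolute"
) -> float:
    """Supra-threshold cut for a BSR map.

    mode="absolute" (default): the stated percentile of |BSR|, applied
    symmetrically — positive edges need BSR >= +T, negative BSR <= -T.
    mode="signed": the percentile of the signed values (sensitivity variant).
    Linear interpolation between order statistics; ties at exactly T count as
    supra-threshold.
    """
    bsr = np.asarray(bsr, dtype=float).ravel()
    if bsr.size == 0:
        raise ValueError("empty BSR input")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if mode == "absolute":
        return float(np.percentile(np.abs(bsr), percentile))
    if mode == "signed":
        return float(np.percentile(bsr, percentile))
    raise ValueError(f"unknown mode {mode!r}")


def band_reduce(
    bsr: np.ndarray,
    freqs: np.ndarray,
    threshold: float,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Extremal supra-threshold BSR per band and feature.

    Parameters
    ----------
    bsr : array (n_freq, n_features)
        BSR map for one latent variable; features are node-pairs (or nodes).
    freqs : array (n_freq,)
        Bin center frequencies in Hz.
    threshold : float
        Symmetric supra-threshold cut (from :func:`bsr_threshold`).

    Returns
    -------
    DataFrame with columns ``band, feature, sign, bsr, freq`` holding, for
    each band and feature, the largest positive BSR >= +T and the most
    negative BSR <= -T (rows absent when no bin qualifies).
    """
    bsr = np.asarray(bsr, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if bsr.shape[0] != freqs.shape[0]:
        raise ValueError("bsr rows must match freqs length")
    labels = assign_band_bins(freqs, bands)
    rows = []
    for band in bands:
        sel = labels == band.name
        if not sel.any():
            continue
        sub = bsr[sel]
        fsub = freqs[sel]
        for sign, mask in (("+", sub >= threshold), ("-", sub <= -threshold)):
            any_feat = mask.any(axis=0)
            for feat in np.nonzero(any_feat)[0]:
                vals = np.where(mask[:, feat], sub[:, feat], np.nan)
                k = np.nanargmax(vals) if sign == "+" else np.nanargmin(vals)
                rows.append(
                    {
                        "band": band.name,
                        "feature": int(feat),
                        "sign": sign,
                        "bsr": float(sub[k, feat]),
                        "freq": float(fsub[k]),
                    }
                )
    return pd.DataFrame(rows, columns=["band", "feature", "sign", "bsr", "freq"])


def band_supra_counts(
    bsr: np.ndarray,
    freqs: np.ndarray,
    threshold: float,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Supra-threshold (freq, feature) counts per band and sign.

    The per-band summary used for feature axes that are not node-pairs
    (e.g. the node axis of the power analysis).
    """
    bsr = np.asarray(bsr, dtype=float)
    labels = assign_band_bins(np.asarray(freqs, dtype=float), bands)
    rows = []
    for band in bands:
        sub = bsr[labels == band.name]
        rows.append(
            {
                "band": band.name,
                "n_positive": int((sub >= threshold).sum()),
                "n_negative": int((sub <= -threshold).sum()),
            }
        )
    return pd.DataFrame(rows)


def node_degree(
    edges: pd.DataFrame,
    n_nodes: int | None = None,
) -> dict[int, int]:
    """Distinct-neighbour degree of every node appearing in the edge list.

    ``edges`` needs ``node_i``/``node_j`` columns (any band mix); a neighbour
    connected in several bands counts once.
    """
    g = nx.Graph()
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    for i, j in zip(edges["node_i"], edges["node_j"]):
        if n_nodes is not None and not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError(f"edge ({i}, {j}) references unknown node")
        g.add_edge(int(i), int(j))
    return dict(g.degree())


@dataclass
class BandNetwork:
    """Thresholded signed networks for one latent variable.

    ``edges`` has one row per (band, node-pair, sign): columns
    ``band, node_i, node_j, sign, bsr, freq``.  Degrees are per signed
    network over the union of bands; the high-degree tables mirror the
    printed summary format (Node, Hemisphere, Degree, Band [Hz]).
    """

    edges: pd.DataFrame
    threshold: float
    percentile: float
    bands: Sequence[Band]
    n_nodes: int
    degrees_positive: dict[int, int] = field(default_factory=dict)
    degrees_negative: dict[int, int] = field(default_factory=dict)
    high_degree_positive: pd.DataFrame | None = None
    high_degree_negative: pd.DataFrame | None = None

    def edge_set(self, sign: str, band: str | None = None) -> set[tuple[int, int]]:
        """Unique (i, j) pairs (i<j) of one signed network, optionally one band."""
        sel = self.edges[self.edges["sign"] == sign]
        if band is not None:
            sel = sel[sel["band"] == band]
        return {
            (int(min(i, j)), int(max(i, j)))
            for i, j in zip(sel["node_i"], sel["node_j"])
        }

    def save(self, path: str | Path) -> None:
        """Tab-separated edge list (band, nodes, sign, BSR, extremal frequency)."""
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _high_degree_table(
    edges: pd.DataFrame,
    degrees: Mapping[int, int],
    bands: Sequence[Band],
    min_degree: int,
    atlas=None,
) -> pd.DataFrame:
    lo = {b.name: b.f_lo for b in bands}
    hi = {b.name: b.f_hi for b in bands}
    rows = []
    for node, deg in degrees.items():
        if deg < min_degree:
            continue
        touching = edges[(edges["node_i"] == node) | (edges["node_j"] == node)]
        spans = sorted(set(touching["band"]), key=lambda n: lo[n])
        span = f"{lo[spans[0]]:g}-{hi[spans[-1]]:g}" if spans else ""
        name, hemi = str(node), ""
        if atlas is not None:
            row = atlas.by_index(node)
            name, hemi = row["name"], row["hemisphere"]
        rows.append(
            {"node": name, "hemisphere": hemi, "degree": deg, "band_hz": span}
        )
    out = pd.DataFrame(rows, columns=["node", "hemisphere", "degree", "band_hz"])
    return out.sort_values(
        ["degree", "node"], ascending=[False, True], ignore_index=True
    )


def build_band_network(
    bsr: np.ndarray,
    freqs: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    percentile: float = 99.9,
    bands: Sequence[Band] = DEFAULT_BANDS,
    min_degree: int = 3,
    atlas=None,
    mode: str = "absolute",
) -> BandNetwork:
    """Threshold a (freq x pair) BSR map and summarise the signed networks.

    The pair axis of ``bsr`` must follow ``pairs`` (lexicographic i<j order
    as produced by :func:`statecoh.spectral.enumerate_pairs`).
    """
    n_nodes = int(max(max(p) for p in pairs)) + 1
    threshold = bsr_threshold(bsr, percentile, mode=mode)
    reduced = band_reduce(bsr, freqs, threshold, bands)
    reduced = reduced.assign(
        node_i=[pairs[f][0] for f in reduced["feature"]],
        node_j=[pairs[f][1] for f in reduced["feature"]],
    )[["band", "node_i", "node_j", "sign", "bsr", "freq"]]

    net = BandNetwork(
        edges=reduced,
        threshold=threshold,
        percentile=percentile,
        bands=tuple(bands),
        n_nodes=n_nodes,
    )
    pos = reduced[reduced["sign"] == "+"]
    neg = reduced[reduced["sign"] == "-"]
    net.degrees_positive = node_degree(pos, n_nodes)
    net.degrees_negative = node_degree(neg, n_nodes)
    net.high_degree_positive = _high_degree_table(
        pos, net.degrees_positive, bands, min_degree, atlas
    )
    net.high_degree_negative = _high_degree_table(
        neg, net.degrees_negative, bands, min_degree, atlas
    )
    return net
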