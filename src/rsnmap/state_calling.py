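"""Cell-state assignment from probes, intensities or marker counts.

Three routes, matching how activation states are measured in practice:

* **Probe overlap** — in-situ hybridisation puncta (e.g. *Cxcl9* / *Il12b*
  probes) are assigned to the cell whose footprint they fall in; a cell's
  state is the probe with sufficient overlap volume.
* **Intensity tiers** — a channel intensity (e.g. MHC class II) gated into
  low / intermediate / high tiers by two cutoffs.
* **Marker-count gating** — MERFISH-style cell-by-gene count tables gated
  on lineage markers (XCR1 for cDC1s, CD3E for T cells) and clustered; the
  clusters enriched in a state marker define the state label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .io_tables import SegmentedObject

__all__ = [
    "ProbeCallConfig",
    "IntensityGateConfig",
    "MerfishGateConfig",
    "call_probe_states",
    "call_intensity_states",
    "call_merfish_states",
]

_PROBE_CLASSES = {"probe_Cxcl9": "Cxcl9", "probe_Il12b": "Il12b"}


@dataclass
class ProbeCallConfig:
    """Probe-overlap state calling parameters.

    ``min_overlap_volume`` is the total probe volume (µm³) inside a cell's
    disc-equivalent footprint required to call the state; the default (any
    positive overlap) mirrors overlap-based classification where no
    explicit minimum is imposed. Cells above threshold for both probes are
    resolved by ``tie_rule``: left unclassified (default) or by argmax.
    """

    min_overlap_volume: float = 0.0
    tie_rule: str = "unclassified"

    def __post_init__(self) -> None:
        if self.min_overlap_volume < 0:
            raise ValueError("min_overlap_volume must be >= 0")
        if self.tie_rule not in ("unclassified", "argmax"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass
class IntensityGateConfig:
    """Two-cutoff tier gate on one channel: low / int / high (left-closed)."""

    channel: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low cutoff must be below high cutoff")


@dataclass
class MerfishGateConfig:
    """MERFISH state-calling gates and clustering parameters.

    ``xcr1_min`` keeps cells with XCR1 counts at or above 3 in the cDC1
    branch (counts below 3 are filtered out); ``cd3e_min`` keeps cells
    with CD3E counts strictly above 5 in the T branch.
    """

    xcr1_min: int = 3
    cd3e_min: int = 5
    n_state_clusters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xcr1_min < 0 or self.cd3e_min < 0:
            raise ValueError("gate thresholds must be non-negative")


def probe_overlap_volumes(
    cells: list[SegmentedObject],
    probe_objects: list[SegmentedObject],
) -> dict[str, np.ndarray]:
    """Total probe volume per cell and probe state.

    A probe object contributes its whole volume to a cell when its centroid
    lies within the cell's effective (disc-equivalent) radius. Returns a
    map probe-state -> per-cell overlap volume array.
    """
    for p in probe_objects:
        if p.object_class not in _PROBE_CLASSES:
            raise ValueError(f"object {p.id} is not a probe (class {p.object_class})")
    n = len(cells)
    out = {state: np.zeros(n) for state in _PROBE_CLASSES.values()}
    if n == 0 or not probe_objects:
        return out
    cell_xy = np.array([(c.x, c.y) for c in cells])
    radii = np.array([c.effective_radius for c in cells])
    rmax = radii.max()
    if rmax == 0:
        return out
    by_state: dict[str, list[SegmentedObject]] = {}
    for p in probe_objects:
        by_state.setdefault(_PROBE_CLASSES[p.object_class], []).append(p)
    for state, probes in by_state.items():
        pts = np.array([(p.x, p.y) for p in probes])
        vols = np.array([p.volume for p in probes])
        tree = cKDTree(pts)
        hits = tree.query_ball_point(cell_xy, r=rmax)
        for i, idx in enumerate(hits):
            if not idx or radii[i] == 0:
                continue
            idx = np.asarray(idx)
            d = np.linalg.norm(pts[idx] - cell_xy[i], axis=1)
            inside = idx[d <= radii[i]]
            out[state][i] = vols[inside].sum()
    return out


def call_probe_states(
    cells: list[SegmentedObject],
    probe_objects: list[SegmentedObject],
    cfg: ProbeCallConfig | None = None,
) -> list[str]:
    """State per cell from probe overlap: "Cxcl9", "Il12b" or "none"."""
    cfg = cfg or ProbeCallConfig()
    overlaps = probe_overlap_volumes(cells, probe_objects)
    states = sorted(overlaps)
    labels = []
    thr = cfg.min_overlap_volume
    for i in range(len(cells)):
        # threshold 0 means "any positive overlap"; otherwise >= threshold
        above = [
            s for s in states
            if (overlaps[s][i] > 0 if thr == 0 else overlaps[s][i] >= thr)
        ]
        if not above:
            labels.append("none")
        elif len(above) == 1:
            labels.append(above[0])
        elif cfg.tie_rule == "argmax":
            vals = {s: overlaps[s][i] for s in above}
            best = max(vals.values())
            winners = sorted(s for s, v in vals.items() if v == best)
            labels.append(winners[0] if len(winners) == 1 else "none")
        else:
            labels.append("none")
    return labels


def call_intensity_states(
    cells: list[SegmentedObject], cfg: IntensityGateConfig
) -> list[str]:
    """Tier per cell: intensity < low -> "low"; < high -> "int"; else "high"."""
    labels = []
    for c in cells:
        if cfg.channel not in c.intensities:
            raise KeyError(f"cell {c.id} lacks channel {cfg.channel!r}")
        v = c.intensities[cfg.channel]
        labels.append("low" if v < cfg.low else ("int" if v < cfg.high else "high"))
    return labels


_REQUIRED_PANEL = ("XCR1", "CLEC9A", "CCR7", "CXCL9", "IL12B", "CD3E", "CD8", "TCF7")


def call_merfish_states(
    counts: pd.DataFrame, cfg: MerfishGateConfig | None = None
) -> pd.Series:
    """Label MERFISH cells from marker counts.

    cDC1 branch: cells with XCR1 >= 3 are log1p-transformed and k-means
    clustered; clusters whose mean CCR7 exceeds both the cluster mean CXCL9
    and the branch-wide CCR7 mean are labelled ``CCR7_cDC1`` (and
    symmetrically ``CXCL9_cDC1``); other clusters stay ``other``.

    T branch: cells with CD3E > 5 are clustered the same way; clusters with
    TCF7 mean above the branch TCF7 mean are ``TCF1pos_T``; remaining
    clusters with CD8 mean above the branch CD8 mean are ``TCF1neg_CD8T``.

    Cells may satisfy both gates; the cDC1 branch takes precedence for
    non-``other`` labels. Returns a per-cell label Series indexed like
    ``counts``.
    """
    cfg = cfg or MerfishGateConfig()
    missing = [g for g in _REQUIRED_PANEL if g not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks panel genes: {missing}")
    labels = pd.Series("other", index=counts.index, dtype=object)

    def _cluster(sub: pd.DataFrame) -> np.ndarray:
        x = np.log1p(sub.to_numpy(dtype=float))
        k = min(cfg.n_state_clusters, len(np.unique(x, axis=0)))
        if k < 2:
            return np.zeros(len(sub), dtype=int)
        km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed)
        return km.fit_predict(x)

    # T branch first so that doubly-gated cells end with the cDC1 call
    t_mask = counts["CD3E"] > cfg.cd3e_min
    if t_mask.any():
        sub = counts.loc[t_mask]
        cl = _cluster(sub)
        tcf7_global = sub["TCF7"].mean()
        cd8_global = sub["CD8"].mean()
        for u in np.unique(cl):
            members = sub.index[cl == u]
            if sub.loc[members, "TCF7"].mean() > tcf7_global:
                labels.loc[members] = "TCF1pos_T"
            elif sub.loc[members, "CD8"].mean() > cd8_global:
                labels.loc[members] = "TCF1neg_CD8T"
    else:
        warnings.warn("no cells pass the CD3E gate; T branch empty")

    dc_mask = counts["XCR1"] >= cfg.xcr1_min
    if dc_mask.any():
        sub = counts.loc[dc_mask]
        cl = _cluster(sub)
        ccr7_global = sub["CCR7"].mean()
        cxcl9_global = sub["CXCL9"].mean()
        for u in np.unique(cl):
            members = sub.index[cl == u]
            ccr7 = sub.loc[members, "CCR7"].mean()
            cxcl9 = sub.loc[members, "CXCL9"].mean()
            if ccr7 > cxcl9 and ccr7 > ccr7_global:
                labels.loc[members] = "CCR7_cDC1"
            elif cxcl9 > ccr7 and cxcl9 > cxcl9_global:
                labels.loc[members] = "CXCL9_cDC1"
    else:
        warnings.warn("no cells pass the XCR1 gate; cDC1 branch empty")

    return labels
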