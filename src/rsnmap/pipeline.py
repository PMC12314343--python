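"""End-to-end orchestration and the paired enrichment statistic.

``run_region_analysis`` pools the raster neighbourhoods of several
sections, clusters them into regions and writes composition, interaction
and per-cell distribution tables. ``run_association_analysis`` builds, per
section, the TCF1+ CD8 T cell density mask, measures each cDC1 state's
percentage within the association distance (10 µm) of the mask, and
compares the paired per-section percentages with a two-tailed paired
t-test — the headline statistic of the analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_tables import SectionDataset
from .neighborhoods import build_raster_grid, count_in_neighborhoods
from .regions import (
    RegionModel,
    assign_cell_regions,
    cluster_neighborhoods,
    distribution_by_region,
    neighborhood_count_matrix,
    normalize_compositions,
    region_composition,
    region_interaction,
    select_num_regions,
)
from .masks import (
    DEFAULT_BANDWIDTH,
    DEFAULT_MASK_SPACING,
    density_mask_from_points,
    distance_to_mask,
    fraction_within,
)
from .state_calling import ProbeCallConfig, call_probe_states

logger = logging.getLogger("rsnmap")

__all__ = [
    "PipelineConfig",
    "EnrichmentResult",
    "paired_t_test",
    "run_region_analysis",
    "run_association_analysis",
]


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the reference analysis values:
    50 µm neighbourhood radius, 100 µm density bandwidth, 10 µm
    association distance, 50 µm border gate."""

    radius: float = 50.0
    spacing: float = 50.0
    k: int | str = 6
    normalization: str = "p95"
    method: str = "som"
    bandwidth: float = DEFAULT_BANDWIDTH
    mask_spacing: float = DEFAULT_MASK_SPACING
    threshold_mode: str = "relative_max"
    threshold_value: float = 0.2
    association_distance: float = 10.0
    border_gate: float = 50.0
    seed: int = 0
    min_overlap_volume: float = 0.0

    def __post_init__(self) -> None:
        for name in ("radius", "spacing", "bandwidth", "mask_spacing",
                     "association_distance", "border_gate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EnrichmentResult:
    """Paired per-section enrichment values and their t-test."""

    section_ids: list[str]
    values_a: np.ndarray  # e.g. % Il12b cDC1s within 10 µm of the mask
    values_b: np.ndarray  # e.g. % Cxcl9 cDC1s
    label_a: str
    label_b: str
    t: float
    df: int
    p: float

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.values_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.values_b))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "section_id": self.section_ids,
                self.label_a: self.values_a,
                self.label_b: self.values_b,
            }
        )


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed paired t-test from its definition.

    t = mean(d) / (sd(d)/sqrt(n)) on the differences d = x - y, with
    n - 1 degrees of freedom and the two-tailed p from the t distribution.
    Identical differences (zero variance) are a degenerate input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("paired differences have zero variance; t undefined")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


def run_region_analysis(
    sections: list[SectionDataset],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cluster pooled neighbourhoods into regions and summarise them.

    Returns a dict with the fitted :class:`RegionModel`, per-section
    neighbourhood tables (with region labels), the composition heatmap
    table, per-section interaction matrices and the per-class cell
    distribution across regions. Writes CSVs plus a JSON manifest when
    ``out_dir`` is given.
    """
    cfg = cfg or PipelineConfig()
    if not sections:
        raise ValueError("need at least one section")
    grids = []
    nbhds_per_section = []
    for ds in sections:
        grid = build_raster_grid(ds.bbox, cfg.spacing)
        nbhds = count_in_neighborhoods(
            [o for o in ds.objects if not o.object_class.startswith("probe_")],
            grid,
            cfg.radius,
        )
        grids.append(grid)
        nbhds_per_section.append(nbhds)
    all_nbhds = [nb for nbs in nbhds_per_section for nb in nbs]
    classes = sorted({c for nb in all_nbhds for c in nb.counts})
    matrix, classes = neighborhood_count_matrix(all_nbhds, classes)
    norm, scale = normalize_compositions(matrix, cfg.normalization)

    if cfg.k == "auto":
        selection = select_num_regions(norm, seeds=[cfg.seed], method=cfg.method)
        k = selection.chosen_k
    else:
        selection = None
        k = int(cfg.k)
    labels, prototypes = cluster_neighborhoods(norm, k, method=cfg.method, seed=cfg.seed)
    model = RegionModel(
        k=k, prototypes=prototypes, classes=classes,
        normalization=cfg.normalization, scale=scale,
    )
    composition = region_composition(all_nbhds, labels, classes)

    offset = 0
    section_tables = []
    interactions = {}
    cell_rows = []
    for ds, grid, nbhds in zip(sections, grids, nbhds_per_section):
        sec_labels = labels[offset: offset + len(nbhds)]
        offset += len(nbhds)
        for nb, lab in zip(nbhds, sec_labels):
            nb.region = int(lab)
        table = pd.DataFrame(
            {
                "center_x": grid.centers[:, 0],
                "center_y": grid.centers[:, 1],
                **{c: [nb.counts.get(c, 0) for nb in nbhds] for c in classes},
                "region": sec_labels,
            }
        )
        section_tables.append((ds.section_id, table))
        interactions[ds.section_id] = region_interaction(grid, sec_labels)
        cells = [o for o in ds.objects if not o.object_class.startswith("probe_")]
        if cells:
            xy = np.array([(o.x, o.y) for o in cells])
            cell_regions = assign_cell_regions(xy, grid, sec_labels)
            for o, r in zip(cells, cell_regions):
                cell_rows.append(
                    {
                        "section_id": ds.section_id,
                        "cell_id": o.id,
                        "object_class": o.object_class,
                        "region": int(r),
                        **{f"label_{k_}": v for k_, v in o.labels.items()},
                    }
                )
    cell_table = pd.DataFrame(cell_rows)
    distribution = (
        distribution_by_region(cell_table) if len(cell_table) else pd.DataFrame()
    )

    result = {
        "model": model,
        "selection": selection,
        "neighborhood_tables": section_tables,
        "composition": composition,
        "interactions": interactions,
        "cell_table": cell_table,
        "distribution": distribution,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, table in section_tables:
            table.to_csv(out / f"neighbourhoods_{sid}.csv", index=False)
        composition.to_csv(out / "region_composition.csv")
        for sid, mat in interactions.items():
            mat.to_csv(out / f"interaction_{sid}.csv")
        if len(cell_table):
            cell_table.to_csv(out / "cell_regions.csv", index=False)
        if len(distribution):
            distribution.to_csv(out / "region_distribution.csv", index=False)
        manifest = {
            "stage": "regions",
            "config": asdict(cfg),
            "k": k,
            "classes": classes,
            "sections": [ds.section_id for ds in sections],
            "n_neighbourhoods": len(all_nbhds),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def _section_state_fractions(
    ds: SectionDataset, cfg: PipelineConfig
) -> tuple[float, float] | None:
    """Per-section (% Il12b cDC1, % Cxcl9 cDC1) within the association
    distance of the TCF1+ CD8 density mask, or None when undefined."""
    cdc1 = ds.of_class("cDC1")
    cd8 = ds.of_class("CD8T")
    tcf1_pos = np.array(
        [(o.x, o.y) for o in cd8 if o.labels.get("tcf1") == "pos"]
    )
    if len(tcf1_pos) < 2 or not cdc1:
        logger.warning("section %s: too few TCF1+ CD8 cells or no cDC1s", ds.section_id)
        return None
    # call cDC1 states from probe puncta when not already labelled
    states = [o.labels.get("state") for o in cdc1]
    if any(s is None for s in states):
        probes = [o for o in ds.objects if o.object_class.startswith("probe_")]
        states = call_probe_states(
            cdc1, probes, ProbeCallConfig(min_overlap_volume=cfg.min_overlap_volume)
        )
    mask = density_mask_from_points(
        np.asarray(tcf1_pos),
        ds.bbox,
        bandwidth=cfg.bandwidth,
        spacing=cfg.mask_spacing,
        threshold_mode=cfg.threshold_mode,
        threshold_value=cfg.threshold_value,
    )
    out = []
    for state in ("Il12b", "Cxcl9"):
        pts = np.array(
            [(o.x, o.y) for o, s in zip(cdc1, states) if s == state]
        )
        if len(pts) == 0:
            logger.warning("section %s: no %s cDC1s", ds.section_id, state)
            return None
        out.append(fraction_within(distance_to_mask(pts, mask), cfg.association_distance))
    return out[0], out[1]


def run_association_analysis(
    sections: list[SectionDataset],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> EnrichmentResult:
    """Paired comparison of cDC1-state association with TCF1+ regions.

    For each section: a kernel-density mask of TCF1+ CD8 T cells, the
    percentage of Il12b and of Cxcl9 cDC1s within the association distance
    of that mask, and finally a two-tailed paired t-test across sections.
    """
    cfg = cfg or PipelineConfig()
    if len(sections) < 2:
        raise ValueError("need at least two sections for a paired test")
    ids, a_vals, b_vals = [], [], []
    for ds in sections:
        fr = _section_state_fractions(ds, cfg)
        if fr is None:
            continue
        ids.append(ds.section_id)
        a_vals.append(fr[0])
        b_vals.append(fr[1])
    if len(ids) < 2:
        raise ValueError("fewer than two sections yielded paired fractions")
    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    t, df, p = paired_t_test(a, b)
    result = EnrichmentResult(
        section_ids=ids, values_a=a, values_b=b,
        label_a="pct_Il12b_within", label_b="pct_Cxcl9_within",
        t=t, df=df, p=p,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(out / "association_fractions.csv", index=False)
        manifest = {
            "stage": "associate",
            "config": asdict(cfg),
            "t": t,
            "df": df,
            "p": p,
            "mean_pct_Il12b": result.mean_a,
            "mean_pct_Cxcl9": result.mean_b,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
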