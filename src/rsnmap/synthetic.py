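"""Synthetic tumour-section generator with planted spatial structure.

Emulates the geometry the analysis assumes: an elliptical tumour in a
rectangular section, a border band at the tumour edge, and six composition
archetypes — CD8-only pockets, cDC1-only pockets, vessel+CD8 areas, poorly
infiltrated tumour, the mixed border band, and infiltrated tumour
parenchyma. Objects of each class are placed by an inhomogeneous Poisson
process whose piecewise-constant rate map is driven by the archetype at
each location (pockets are seeded on a coarse block grid).

Cell states carry the planted spatial bias the association statistics are
meant to detect: Il12b cDC1s and TCF1+ CD8 T cells are enriched in the
border band, Cxcl9 cDC1s and TCF1- CD8 T cells in the parenchyma. Probe
puncta are attached to cDC1s according to their true state. A serial-pair
generator applies a known smooth warp (affine + sinusoidal displacement)
with thinning and jitter, and a MERFISH-style generator draws
negative-binomial marker counts from latent cell types with the same
spatial biases.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_tables import SectionDataset, SegmentedObject

__all__ = [
    "ARCHETYPES",
    "SectionConfig",
    "GroundTruth",
    "TrueWarp",
    "generate_section",
    "generate_serial_pair",
    "generate_merfish_table",
    "MERFISH_PANEL",
]

#: Archetype order used throughout; indices are the ground-truth labels.
ARCHETYPES = ("CD8", "cDC1", "vessel", "Tumour", "Border", "infTumour")

_CLASSES = ("cDC1", "CD8T", "CD4T", "vessel", "tumour")

#: Mean object counts per archetype within one reference neighbourhood
#: (50 µm-radius disc, ~7854 µm²), mirroring the six composition
#: archetypes: pockets dominated by CD8 T cells or cDC1s, vessel-rich
#: areas, poorly infiltrated tumour, the mixed border and infiltrated
#: parenchyma. Densities (~1-5 x 10^-3 cells/µm² in dense areas) are
#: typical of lymphocyte-rich tumour tissue. CD4 T cells are supported as
#: a class but take no part in the four-class region layout, so their
#: default rate is 0.
DEFAULT_ARCHETYPE_MEANS: dict[str, dict[str, float]] = {
    "CD8": {"cDC1": 0.6, "CD8T": 30.0, "CD4T": 0.0, "vessel": 1.0, "tumour": 0.6},
    "cDC1": {"cDC1": 30.0, "CD8T": 0.6, "CD4T": 0.0, "vessel": 1.0, "tumour": 0.6},
    "vessel": {"cDC1": 1.0, "CD8T": 9.0, "CD4T": 0.0, "vessel": 30.0, "tumour": 1.0},
    "Tumour": {"cDC1": 0.6, "CD8T": 1.0, "CD4T": 0.0, "vessel": 1.5, "tumour": 36.0},
    "Border": {"cDC1": 24.0, "CD8T": 24.0, "CD4T": 0.0, "vessel": 18.0, "tumour": 12.0},
    "infTumour": {"cDC1": 1.5, "CD8T": 21.0, "CD4T": 0.0, "vessel": 9.0, "tumour": 30.0},
}

#: Mean probe puncta per cDC1 by true state: the matched probe is abundant,
#: the other probe rare (off-target / segmentation spill-over).
DEFAULT_PUNCTA_PER_STATE: dict[str, dict[str, float]] = {
    "Il12b": {"Il12b": 5.0, "Cxcl9": 0.05},
    "Cxcl9": {"Cxcl9": 5.0, "Il12b": 0.05},
}

#: Typical cell volumes (µm³) used to draw per-object volumes; the cDC1
#: value gives a ~7 µm disc-equivalent radius for puncta capture.
DEFAULT_MEAN_VOLUMES: dict[str, float] = {
    "cDC1": 150.0,
    "CD8T": 120.0,
    "CD4T": 120.0,
    "vessel": 2000.0,
    "tumour": 2000.0,
}

MERFISH_PANEL = ("XCR1", "CLEC9A", "CCR7", "CXCL9", "IL12B", "CD3E", "CD8", "TCF7")

MERFISH_TYPES = ("CCR7_cDC1", "CXCL9_cDC1", "TCF1pos_T", "TCF1neg_CD8T", "other")

#: Negative-binomial mean counts per latent type: each marker is high
#: (>= 10) in its own type and low (<= 1) elsewhere.
DEFAULT_MERFISH_MEANS: dict[str, dict[str, float]] = {
    "CCR7_cDC1": {"XCR1": 15, "CLEC9A": 12, "CCR7": 15, "CXCL9": 0.5,
                  "IL12B": 10, "CD3E": 0.3, "CD8": 0.2, "TCF7": 0.3},
    "CXCL9_cDC1": {"XCR1": 15, "CLEC9A": 12, "CCR7": 0.5, "CXCL9": 15,
                   "IL12B": 0.3, "CD3E": 0.3, "CD8": 0.2, "TCF7": 0.3},
    "TCF1pos_T": {"XCR1": 0.2, "CLEC9A": 0.2, "CCR7": 0.5, "CXCL9": 0.3,
                  "IL12B": 0.1, "CD3E": 15, "CD8": 4, "TCF7": 12},
    "TCF1neg_CD8T": {"XCR1": 0.2, "CLEC9A": 0.2, "CCR7": 0.3, "CXCL9": 0.3,
                     "IL12B": 0.1, "CD3E": 15, "CD8": 12, "TCF7": 0.5},
    "other": {"XCR1": 0.3, "CLEC9A": 0.3, "CCR7": 0.3, "CXCL9": 0.5,
              "IL12B": 0.1, "CD3E": 0.5, "CD8": 0.5, "TCF7": 0.3},
}


@dataclass
class SectionConfig:
    """Stated world of one synthetic section.

    The bbox and tumour ellipse are in µm. ``archetype_means`` are expected
    counts per 50 µm-radius neighbourhood; ``state_biases`` are the
    probabilities that a border-band cDC1 is Il12b (resp. that a
    parenchymal cDC1 is Cxcl9, and that a border CD8 T cell is TCF1+).
    ``noise`` is a uniform background count per neighbourhood per class.
    """

    bbox: tuple[float, float, float, float] = (0.0, 0.0, 4000.0, 4000.0)
    tumour_center: tuple[float, float] | None = None  # default: bbox centre
    tumour_semi_axes: tuple[float, float] = (1300.0, 1000.0)
    border_width: float = 300.0
    pocket_size: float = 1500.0
    reference_radius: float = 50.0
    archetype_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(v) for a, v in DEFAULT_ARCHETYPE_MEANS.items()}
    )
    il12b_border: float = 0.75
    cxcl9_parenchyma: float = 0.75
    tcf1_border: float = 0.75
    puncta_per_state: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_PUNCTA_PER_STATE.items()}
    )
    punctum_volume: float = 1.0
    # uniform background per class; CD4 T cells are not part of the
    # four-class imaging panel, so they default to no background either
    noise: dict[str, float] = field(
        default_factory=lambda: {c: (0.0 if c == "CD4T" else 0.05) for c in _CLASSES}
    )
    mean_volumes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_VOLUMES)
    )
    # serial-pair parameters
    pair_keep_fraction: float = 0.8
    pair_jitter_sigma: float = 5.0
    pair_affine_rotation_deg: float = 2.0
    pair_affine_scale: float = 1.01
    pair_affine_offset: tuple[float, float] = (40.0, -30.0)
    pair_sin_amplitude: float = 30.0
    pair_sin_wavelength: float = 4000.0
    pair_n_landmarks: int = 36
    # MERFISH parameters
    merfish_n_cells: int = 2000
    merfish_dispersion: float = 10.0
    merfish_type_probs: tuple[float, ...] = (0.10, 0.10, 0.20, 0.20, 0.40)
    merfish_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_MERFISH_MEANS.items()}
    )

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"bbox {self.bbox} has non-positive area")
        if self.tumour_center is None:
            self.tumour_center = ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)
        a, b = self.tumour_semi_axes
        if self.border_width >= min(a, b):
            raise ValueError("border_width must be below the smallest semi-axis")
        for p in (self.il12b_border, self.cxcl9_parenchyma, self.tcf1_border):
            if not 0.0 <= p <= 1.0:
                raise ValueError("state biases must be probabilities")
        for d in (self.archetype_means, ):
            for rates in d.values():
                if any(v < 0 for v in rates.values()):
                    raise ValueError("archetype rates must be >= 0")
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise rates must be >= 0")

    @property
    def neighbourhood_area(self) -> float:
        return math.pi * self.reference_radius**2

    def null_biases(self) -> "SectionConfig":
        """Copy with no spatial state bias (type-I-error experiments)."""
        return replace(self, il12b_border=0.5, cxcl9_parenchyma=0.5, tcf1_border=0.5)

    def scaled(self, factor: float) -> "SectionConfig":
        """Geometrically shrunk copy (densities preserved) for fast
        replicate simulations."""
        if not 0 < factor <= 1:
            raise ValueError("factor must be in (0, 1]")
        xmin, ymin, xmax, ymax = self.bbox
        a, b = self.tumour_semi_axes
        return replace(
            self,
            bbox=(xmin, ymin, xmin + (xmax - xmin) * factor,
                  ymin + (ymax - ymin) * factor),
            tumour_center=None,
            tumour_semi_axes=(a * factor, b * factor),
            border_width=self.border_width * factor,
            pocket_size=self.pocket_size * factor,
            pair_sin_wavelength=self.pair_sin_wavelength * factor,
        )

    # --- geometry -----------------------------------------------------
    def _ellipse_rho(self, pts: np.ndarray, shrink: float) -> np.ndarray:
        cx, cy = self.tumour_center
        a, b = self.tumour_semi_axes
        a, b = a + shrink, b + shrink
        return ((pts[:, 0] - cx) / a) ** 2 + ((pts[:, 1] - cy) / b) ** 2

    def zone_at(self, points: np.ndarray) -> np.ndarray:
        """0 = tumour core, 1 = border band, 2 = stroma.

        The band lies between two ellipses whose semi-axes are offset by
        +-border_width/2 around the tumour outline.
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        h = self.border_width / 2.0
        inner = self._ellipse_rho(pts, -h) <= 1.0
        outer = self._ellipse_rho(pts, +h) <= 1.0
        return np.where(inner, 0, np.where(outer, 1, 2))

    def zone_areas(self) -> tuple[float, float, float]:
        """(core, band, stroma) areas in µm²."""
        xmin, ymin, xmax, ymax = self.bbox
        a, b = self.tumour_semi_axes
        h = self.border_width / 2.0
        core = math.pi * (a - h) * (b - h)
        outer = math.pi * (a + h) * (b + h)
        total = (xmax - xmin) * (ymax - ymin)
        return core, outer - core, total - outer


@dataclass
class TrueWarp:
    """Planted serial-pair warp: affine map plus sinusoidal displacement."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    amplitude: float
    wavelength: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        out = pts @ self.matrix.T + self.offset
        if self.amplitude != 0:
            w = 2 * np.pi / self.wavelength
            out = out + self.amplitude * np.column_stack(
                [np.sin(w * pts[:, 1]), np.sin(w * pts[:, 0])]
            )
        return out


@dataclass
class GroundTruth:
    """Everything a recovery test needs to know about a generated section."""

    config: SectionConfig
    pocket_core: np.ndarray  # (nby, nbx) archetype index (3 or 5) per block
    pocket_stroma: np.ndarray  # (nby, nbx) archetype index (0, 1 or 2)
    object_archetype: dict[int, int] = field(default_factory=dict)
    cdc1_state: dict[int, str] = field(default_factory=dict)
    cd8_tcf1: dict[int, str] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    warp: TrueWarp | None = None

    def archetype_at(self, points: np.ndarray) -> np.ndarray:
        """Planted archetype index (0..5) at each location."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        zone = self.config.zone_at(pts)
        xmin, ymin, _, _ = self.config.bbox
        ps = self.config.pocket_size
        nby, nbx = self.pocket_core.shape
        bi = np.clip(((pts[:, 0] - xmin) / ps).astype(int), 0, nbx - 1)
        bj = np.clip(((pts[:, 1] - ymin) / ps).astype(int), 0, nby - 1)
        out = np.where(
            zone == 0,
            self.pocket_core[bj, bi],
            np.where(zone == 1, 4, self.pocket_stroma[bj, bi]),
        )
        return out

    def expected_class_counts(self) -> dict[str, float]:
        """Analytic expectation of per-class totals under the rate maps
        (pocket choices averaged out)."""
        cfg = self.config
        core_area, band_area, stroma_area = cfg.zone_areas()
        xmin, ymin, xmax, ymax = cfg.bbox
        total_area = (xmax - xmin) * (ymax - ymin)
        a_nb = cfg.neighbourhood_area
        m = cfg.archetype_means
        out = {}
        for cls in _CLASSES:
            core_rate = (m["Tumour"][cls] + m["infTumour"][cls]) / 2.0
            stroma_rate = (m["CD8"][cls] + m["cDC1"][cls] + m["vessel"][cls]) / 3.0
            expected = (
                core_area * core_rate
                + band_area * m["Border"][cls]
                + stroma_area * stroma_rate
                + total_area * cfg.noise.get(cls, 0.0)
            ) / a_nb
            out[cls] = expected
        return out


def _sample_class_points(
    cfg: SectionConfig, truth: GroundTruth, cls: str, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson sample of one class via thinning."""
    xmin, ymin, xmax, ymax = cfg.bbox
    area = (xmax - xmin) * (ymax - ymin)
    a_nb = cfg.neighbourhood_area
    rates = np.array([cfg.archetype_means[a][cls] for a in ARCHETYPES])
    noise = cfg.noise.get(cls, 0.0)
    lam_max = (rates.max() + noise) / a_nb
    if lam_max == 0:
        return np.empty((0, 2))
    n = rng.poisson(lam_max * area)
    if n == 0:
        return np.empty((0, 2))
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n), rng.uniform(ymin, ymax, n)]
    )
    arch = truth.archetype_at(pts)
    lam = (rates[arch] + noise) / a_nb
    keep = rng.uniform(0, 1, n) < lam / lam_max
    return pts[keep]


def generate_section(
    cfg: SectionConfig | None = None,
    seed: int = 0,
    section_id: str | None = None,
    include_probes: bool = True,
) -> tuple[SectionDataset, GroundTruth]:
    """Generate one section and its ground truth.

    Placement is an inhomogeneous Poisson process per class over the
    archetype rate map. cDC1 states and CD8 TCF1 states are drawn
    conditionally on the zone: a border-band cDC1 is Il12b with
    probability ``il12b_border`` (default 0.75) and a parenchymal or
    stromal cDC1 is Cxcl9 with probability ``cxcl9_parenchyma`` — the
    planted enrichment of Il12b cDC1s (and TCF1+ CD8 T cells) at the
    tumour border. TCF1 status is stored on the CD8 objects (it is an
    imaging stain in the emulated workflow); cDC1 states live only in the
    ground truth and must be recovered from the planted probe puncta.
    """
    cfg = cfg or SectionConfig()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = cfg.bbox
    nbx = max(1, int(math.ceil((xmax - xmin) / cfg.pocket_size)))
    nby = max(1, int(math.ceil((ymax - ymin) / cfg.pocket_size)))
    pocket_core = rng.choice([3, 5], size=(nby, nbx))
    pocket_stroma = rng.choice([0, 1, 2], size=(nby, nbx))
    truth = GroundTruth(config=cfg, pocket_core=pocket_core, pocket_stroma=pocket_stroma)

    objects: list[SegmentedObject] = []
    next_id = 0
    for cls in _CLASSES:
        pts = _sample_class_points(cfg, truth, cls, rng)
        truth.class_counts[cls] = len(pts)
        if len(pts) == 0:
            continue
        arch = truth.archetype_at(pts)
        zone = cfg.zone_at(pts)
        mean_vol = cfg.mean_volumes.get(cls, 100.0)
        # gamma with shape 9 -> CV ~0.33 around the class-typical volume
        vols = rng.gamma(9.0, mean_vol / 9.0, size=len(pts))
        states: list[dict[str, str]] = [{} for _ in range(len(pts))]
        if cls == "cDC1":
            p_il12b = np.where(zone == 1, cfg.il12b_border, 1.0 - cfg.cxcl9_parenchyma)
            is_il12b = rng.uniform(0, 1, len(pts)) < p_il12b
            for i, flag in enumerate(is_il12b):
                truth.cdc1_state[next_id + i] = "Il12b" if flag else "Cxcl9"
        elif cls == "CD8T":
            p_pos = np.where(zone == 1, cfg.tcf1_border, 1.0 - cfg.tcf1_border)
            is_pos = rng.uniform(0, 1, len(pts)) < p_pos
            for i, flag in enumerate(is_pos):
                lbl = "pos" if flag else "neg"
                truth.cd8_tcf1[next_id + i] = lbl
                states[i]["tcf1"] = lbl
        for i in range(len(pts)):
            truth.object_archetype[next_id + i] = int(arch[i])
            objects.append(
                SegmentedObject(
                    id=next_id + i,
                    object_class=cls,
                    x=float(pts[i, 0]),
                    y=float(pts[i, 1]),
                    volume=float(vols[i]),
                    labels=states[i],
                )
            )
        next_id += len(pts)

    # probe puncta around each cDC1 according to its true state
    probe_objs: list[SegmentedObject] = []
    cdc1_parents = [o for o in objects if o.object_class == "cDC1"] if include_probes else []
    for o in cdc1_parents:
        state = truth.cdc1_state[o.id]
        r_cell = o.effective_radius
        for probe, mean in sorted(cfg.puncta_per_state[state].items()):
            n = rng.poisson(mean)
            if n == 0:
                continue
            rr = r_cell * np.sqrt(rng.uniform(0, 1, n))
            th = rng.uniform(0, 2 * np.pi, n)
            for j in range(n):
                # keep puncta of edge cells inside the section bbox
                px = min(max(o.x + rr[j] * np.cos(th[j]), xmin), xmax)
                py = min(max(o.y + rr[j] * np.sin(th[j]), ymin), ymax)
                probe_objs.append(
                    SegmentedObject(
                        id=next_id,
                        object_class=f"probe_{probe}",
                        x=float(px),
                        y=float(py),
                        volume=cfg.punctum_volume,
                    )
                )
                next_id += 1
    objects.extend(probe_objs)
    truth.class_counts["probe_Cxcl9"] = sum(
        1 for o in probe_objs if o.object_class == "probe_Cxcl9"
    )
    truth.class_counts["probe_Il12b"] = sum(
        1 for o in probe_objs if o.object_class == "probe_Il12b"
    )
    ds = SectionDataset(
        section_id=section_id or f"synthetic-{seed}",
        objects=objects,
        bbox=cfg.bbox,
    )
    return ds, truth


def generate_serial_pair(
    cfg: SectionConfig | None = None, seed: int = 0
) -> tuple[SectionDataset, SectionDataset, TrueWarp, tuple[np.ndarray, np.ndarray]]:
    """Generate a serial-section pair related by a known smooth warp.

    Section B is section A with objects independently thinned
    (``pair_keep_fraction``), jittered (``pair_jitter_sigma`` µm, isotropic
    Gaussian — biological non-correspondence between adjacent sections)
    and mapped through the true warp: a mild affine map plus a sinusoidal
    displacement field of amplitude ``pair_sin_amplitude``. Landmark pairs
    lie exactly on the true warp, on a regular grid dense enough to resolve
    the displacement wavelength.
    """
    cfg = cfg or SectionConfig()
    section_a, truth = generate_section(cfg, seed, section_id=f"serialA-{seed}")
    rng = np.random.default_rng(seed + 1_000_003)

    theta = np.deg2rad(cfg.pair_affine_rotation_deg)
    matrix = cfg.pair_affine_scale * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    offset = np.array(cfg.pair_affine_offset, dtype=float)
    warp = TrueWarp(
        matrix=matrix,
        offset=offset,
        amplitude=cfg.pair_sin_amplitude,
        wavelength=cfg.pair_sin_wavelength,
    )
    truth.warp = warp

    objs_b: list[SegmentedObject] = []
    oid = 0
    for o in section_a.objects:
        if cfg.pair_keep_fraction < 1.0 and rng.uniform() >= cfg.pair_keep_fraction:
            continue
        jit = (
            rng.normal(0.0, cfg.pair_jitter_sigma, 2)
            if cfg.pair_jitter_sigma > 0
            else np.zeros(2)
        )
        new_xy = warp(np.array([[o.x + jit[0], o.y + jit[1]]]))[0]
        objs_b.append(
            SegmentedObject(
                id=oid,
                object_class=o.object_class,
                x=float(new_xy[0]),
                y=float(new_xy[1]),
                volume=o.volume,
                intensities=dict(o.intensities),
                labels=dict(o.labels),
            )
        )
        oid += 1
    xs = [o.x for o in objs_b] or [0.0, 1.0]
    ys = [o.y for o in objs_b] or [0.0, 1.0]
    bbox_b = (min(xs) - 1.0, min(ys) - 1.0, max(xs) + 1.0, max(ys) + 1.0)
    section_b = SectionDataset(
        section_id=f"serialB-{seed}", objects=objs_b, bbox=bbox_b
    )

    m = max(3, int(round(math.sqrt(cfg.pair_n_landmarks))))
    xmin, ymin, xmax, ymax = cfg.bbox
    lx = np.linspace(xmin, xmax, m)
    ly = np.linspace(ymin, ymax, m)
    gx, gy = np.meshgrid(lx, ly)
    src = np.column_stack([gx.ravel(), gy.ravel()])
    dst = warp(src)
    return section_a, section_b, warp, (src, dst)


def _sample_zone_points(
    cfg: SectionConfig, n: int, zone: int | None, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points in one zone (None = whole bbox) by rejection."""
    xmin, ymin, xmax, ymax = cfg.bbox
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 64)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        if zone is not None:
            cand = cand[cfg.zone_at(cand) == zone]
        out = np.vstack([out, cand])
    return out[:n]


def generate_merfish_table(
    cfg: SectionConfig | None = None, seed: int = 0
) -> tuple["pd.DataFrame", "pd.DataFrame", np.ndarray]:
    """MERFISH-style cell-by-gene counts with latent cell types.

    Counts are negative-binomial (gamma-Poisson) with type-specific means
    and dispersion ``merfish_dispersion`` (``inf`` = Poisson limit).
    Coordinates carry the same border/parenchyma biases as tissue
    sections: CCR7_cDC1 and TCF1pos_T cells favour the border band,
    CXCL9_cDC1 and TCF1neg_CD8T the tumour parenchyma. Returns (counts,
    coordinates, latent type labels).
    """
    import pandas as pd

    cfg = cfg or SectionConfig()
    for t, means in cfg.merfish_means.items():
        missing = [g for g in MERFISH_PANEL if g not in means]
        if missing:
            raise ValueError(f"type {t} lacks panel genes {missing}")
    rng = np.random.default_rng(seed)
    n = cfg.merfish_n_cells
    probs = np.asarray(cfg.merfish_type_probs, dtype=float)
    probs = probs / probs.sum()
    types = rng.choice(len(MERFISH_TYPES), size=n, p=probs)
    counts = np.zeros((n, len(MERFISH_PANEL)), dtype=int)
    theta = cfg.merfish_dispersion
    for ti, tname in enumerate(MERFISH_TYPES):
        rows = np.nonzero(types == ti)[0]
        if len(rows) == 0:
            continue
        for gi, gene in enumerate(MERFISH_PANEL):
            mu = cfg.merfish_means[tname][gene]
            if np.isinf(theta):
                lam = np.full(len(rows), mu)
            else:
                lam = rng.gamma(theta, mu / theta, size=len(rows))
            counts[rows, gi] = rng.poisson(lam)
    # coordinates, drawn per type with the planted zone biases
    coords = np.zeros((n, 2))
    border_bias = {"CCR7_cDC1": cfg.il12b_border, "TCF1pos_T": cfg.tcf1_border}
    parenchyma_bias = {"CXCL9_cDC1": cfg.cxcl9_parenchyma,
                       "TCF1neg_CD8T": cfg.tcf1_border}
    for ti, tname in enumerate(MERFISH_TYPES):
        rows = np.nonzero(types == ti)[0]
        if len(rows) == 0:
            continue
        if tname in border_bias:
            in_border = rng.uniform(0, 1, len(rows)) < border_bias[tname]
        elif tname in parenchyma_bias:
            in_border = rng.uniform(0, 1, len(rows)) >= parenchyma_bias[tname]
        else:
            coords[rows] = _sample_zone_points(cfg, len(rows), None, rng)
            continue
        nb = int(in_border.sum())
        if nb:
            coords[rows[in_border]] = _sample_zone_points(cfg, nb, 1, rng)
        if len(rows) - nb:
            coords[rows[~in_border]] = _sample_zone_points(
                cfg, len(rows) - nb, 0, rng
            )
    count_df = pd.DataFrame(counts, columns=list(MERFISH_PANEL))
    coord_df = pd.DataFrame(coords, columns=["x", "y"])
    type_labels = np.array([MERFISH_TYPES[t] for t in types])
    return count_df, coord_df, type_labels
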