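"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator emulates one of the raw data types the analysis modules
consume — AFM height maps with oriented stress-fiber texture, scan-line
offsets and dome-shaped protrusions; force-distance curves with a linear
indentation regime and a triangular retraction adhesion dip; fluorescence
images of Gaussian spots or fibers with Poisson-Gaussian noise; and Ct /
protein quantification tables with planted effects — and returns the exact
parameters it used as a :class:`GroundTruth`, so downstream results can be
checked against closed forms.

Determinism: a single top-level seed is expanded into independent
per-component streams through ``numpy.random.SeedSequence`` spawn keys
(height map = 0, force curve = 1, spot image = 2, table = 3, fiber
image = 4), so adding a generator never perturbs existing outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .containers import ForceCurve, HeightMap

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "FiberSpec",
    "BumpSpec",
    "CurveSpec",
    "SpotSpec",
    "TableSpec",
    "FluorFiberSpec",
    "make_height_map",
    "make_force_curve",
    "make_spot_image",
    "make_quant_table",
    "make_fiber_image",
]

# spawn-key indices; fixed forever so fixtures stay stable when generators are added
_COMPONENT = {"height_map": 0, "force_curve": 1, "spot_image": 2, "table": 3, "fiber_image": 4}

PN_NM_TO_J = 1e-21  # 1 pN·nm = 1e-21 J
RESOLVABLE_SEPARATION_SIGMA = 2.5  # Rayleigh-like two-point criterion


@dataclass
class FiberSpec:
    """One family of parallel sinusoidal ridges emulating stress-fiber texture."""

    theta_deg: float = 45.0  # fiber axis orientation, [0, 180)
    period_um: float = 1.25  # ridge-to-ridge spacing
    amplitude_nm: float = 30.0


@dataclass
class BumpSpec:
    """A Gaussian dome emulating a membrane protrusion."""

    center_um: tuple[float, float] = (0.0, 0.0)  # (row, col) position in µm
    height_nm: float = 200.0
    sigma_um: float = 0.5

    @property
    def volume_um3(self) -> float:
        """Analytic full dome volume ∫ h·exp(-r²/2σ²) dA = 2π σ² h."""
        return 2.0 * math.pi * self.sigma_um**2 * self.height_nm * 1e-3


@dataclass
class CurveSpec:
    """Force-curve scenario: linear indentation plus triangular adhesion dip.

    Probe metadata defaults follow a soft-cantilever cell-mechanics setup
    (0.03 N/m spring constant, 2 µm ramp, 10 µm/s speed).
    """

    contact_nm: float = 1000.0
    slope_pn_per_nm: float = 0.05
    ramp_nm: float = 2000.0
    n_samples: int = 2048
    noise_sd_pn: float = 0.0
    dip_depth_pn: float = 0.0
    dip_width_nm: float = 0.0
    baseline_pn: float = 0.0
    baseline_tilt_pn_per_nm: float = 0.0
    spring_constant_N_m: float = 0.03
    speed_um_s: float = 10.0
    contact_time_s: float = 0.0
    setpoint_nN: float = 1.5
    cell_id: str | None = None


@dataclass
class SpotSpec:
    """Gaussian-dot image scenario (proximity-ligation-assay dots)."""

    n_spots: int = 25
    sigma_px: float = 2.0
    amplitude: float = 1000.0
    min_separation_px: float = 12.0
    background: float = 100.0
    poisson: bool = True
    read_noise_sd: float = 0.0
    centers: Sequence[tuple[float, float]] | None = None  # explicit (row, col)
    margin_px: float | None = None  # default 3σ


@dataclass
class TableSpec:
    """Quantification-table scenario: qPCR Ct table or protein abundances."""

    kind: str = "protein"  # "protein" | "ct"
    # protein
    n_rows: int = 1000
    group_sizes: tuple[int, int] = (4, 4)
    group_names: tuple[str, str] = ("WT", "KO")
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    within_sd_log2: float = 0.25
    n_effects: int = 50
    effect_log2fc: float = 1.5
    peptide_lambda: float = 5.0
    frac_single_peptide: float = 0.05
    # ct
    genes: tuple[str, ...] = ("Kcnk2", "Cfl1", "Limk1", "Ssh1")
    housekeeping: tuple[str, ...] = ("Gapdh", "Gusb")
    reference_group: str = "WT"
    planted_ddct: dict[str, float] = field(default_factory=dict)
    ct_noise_sd: float = 0.15
    sample_shift_sd: float = 0.5


@dataclass
class FluorFiberSpec:
    """A straight fluorescent fiber with Gaussian cross-section."""

    p0_um: tuple[float, float] = (2.0, 2.0)  # (row, col) endpoints in µm
    p1_um: tuple[float, float] = (18.0, 18.0)
    amplitude: float = 1000.0
    sigma_um: float = 0.3

    @property
    def length_um(self) -> float:
        return math.dist(self.p0_um, self.p1_um)


@dataclass
class SynthConfig:
    """Top-level generator configuration; unused blocks are ignored."""

    seed: int = 0
    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.156
    noise_sd: float = 0.0
    baseline_nm: float = 0.0
    row_offset_sd_nm: float = 0.0
    fibers: list[FiberSpec] = field(default_factory=list)
    bumps: list[BumpSpec] = field(default_factory=list)
    curve: CurveSpec = field(default_factory=CurveSpec)
    spot: SpotSpec = field(default_factory=SpotSpec)
    table: TableSpec = field(default_factory=TableSpec)
    fluor_fibers: list[FluorFiberSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        r, c = self.image_shape
        if r <= 0 or c <= 0:
            raise ValueError("image_shape entries must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0 or self.row_offset_sd_nm < 0:
            raise ValueError("noise levels must be non-negative")

    def rng(self, component: str) -> np.random.Generator:
        """Independent stream for one generator component."""
        key = _COMPONENT[component]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """True generating parameters, serialized alongside every dataset."""

    scenario: str
    data: dict[str, Any]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["scenario"], d["data"])


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


# ---------------------------------------------------------------------------
# height maps


def make_height_map(cfg: SynthConfig) -> tuple[HeightMap, GroundTruth]:
    """Generate an AFM-like topography: baseline + oriented sinusoidal ridges
    + Gaussian domes + per-row scan offsets + white noise.

    Raises
    ------
    ValueError
        If a fiber period is below 2 pixels (aliased beyond recovery).
    """
    rows, cols = cfg.image_shape
    px = cfg.pixel_size_um
    for f in cfg.fibers:
        if f.period_um / px < 2.0:
            raise ValueError(
                f"fiber period {f.period_um} µm is {f.period_um / px:.2f} px; "
                "periods below 2 px alias and are rejected"
            )

    y = np.arange(rows)[:, None] * px  # µm, slow axis
    x = np.arange(cols)[None, :] * px  # µm, fast axis
    h = np.full((rows, cols), float(cfg.baseline_nm))

    for f in cfg.fibers:
        th = math.radians(f.theta_deg)
        # coordinate perpendicular to the fiber axis
        u = -x * math.sin(th) + y * math.cos(th)
        h += f.amplitude_nm * np.sin(2.0 * np.pi * u / f.period_um)

    for b in cfg.bumps:
        cy, cx = b.center_um
        r2 = (y - cy) ** 2 + (x - cx) ** 2
        h += b.height_nm * np.exp(-r2 / (2.0 * b.sigma_um**2))

    rng = cfg.rng("height_map")
    row_offsets = np.zeros(rows)
    if cfg.row_offset_sd_nm > 0:
        row_offsets = rng.normal(0.0, cfg.row_offset_sd_nm, rows)
        h = h + row_offsets[:, None]
    if cfg.noise_sd > 0:
        h = h + rng.normal(0.0, cfg.noise_sd, (rows, cols))

    truth = GroundTruth(
        "height_map",
        {
            "baseline_nm": cfg.baseline_nm,
            "pixel_size_um": px,
            "fibers": [dataclasses.asdict(f) for f in cfg.fibers],
            "anisotropic": bool(cfg.fibers),
            "bumps": [
                {**dataclasses.asdict(b), "volume_um3": b.volume_um3} for b in cfg.bumps
            ],
            "row_offsets_nm": row_offsets.tolist(),
            "row_offset_sd_nm": cfg.row_offset_sd_nm,
            "noise_sd_nm": cfg.noise_sd,
        },
    )
    hmap = HeightMap(h, px, {"source": "synthgen", "seed": cfg.seed})
    return hmap, truth


# ---------------------------------------------------------------------------
# force curves


def make_force_curve(cfg: SynthConfig) -> tuple[ForceCurve, GroundTruth]:
    """Generate a force-distance curve.

    Approach: noisy baseline for positions above the contact point ``x0``,
    then force rising linearly with slope ``k`` (pN/nm) as the probe indents.
    Retraction mirrors the approach plus a triangular negative dip of depth
    ``F_a`` and base width ``w`` placed just past the contact point, whose
    analytic area is ½·F_a·w.
    """
    c = cfg.curve
    if c.slope_pn_per_nm < 0:
        raise ValueError("stiffness slope must be non-negative")
    if c.dip_depth_pn < 0:
        raise ValueError("adhesion dip depth must be non-negative")
    if c.dip_depth_pn > 0 and c.dip_width_nm <= 0:
        raise ValueError("adhesion dip width must be positive")
    if not (0 <= c.contact_nm <= c.ramp_nm):
        raise ValueError("contact point must lie inside the ramp")
    if c.dip_depth_pn > 0 and c.contact_nm + c.dip_width_nm > c.ramp_nm:
        raise ValueError("adhesion dip extends beyond the ramp")

    rng = cfg.rng("force_curve")
    # approach: far -> near (positions decreasing)
    pos_app = np.linspace(c.ramp_nm, 0.0, c.n_samples)
    baseline = c.baseline_pn + c.baseline_tilt_pn_per_nm * pos_app
    f_app = baseline + c.slope_pn_per_nm * np.maximum(0.0, c.contact_nm - pos_app)
    if c.noise_sd_pn > 0:
        f_app = f_app + rng.normal(0.0, c.noise_sd_pn, c.n_samples)

    # retraction: near -> far, mirror plus adhesion dip
    pos_ret = pos_app[::-1].copy()
    f_ret = (
        c.baseline_pn
        + c.baseline_tilt_pn_per_nm * pos_ret
        + c.slope_pn_per_nm * np.maximum(0.0, c.contact_nm - pos_ret)
    )
    if c.dip_depth_pn > 0:
        half = c.dip_width_nm / 2.0
        center = c.contact_nm + half
        tri = np.maximum(0.0, 1.0 - np.abs(pos_ret - center) / half)
        f_ret = f_ret - c.dip_depth_pn * tri
    if c.noise_sd_pn > 0:
        f_ret = f_ret + rng.normal(0.0, c.noise_sd_pn, c.n_samples)

    meta = {
        "spring_constant_N_m": c.spring_constant_N_m,
        "speed_um_s": c.speed_um_s,
        "contact_time_s": c.contact_time_s,
        "setpoint_nN": c.setpoint_nN,
        "source": "synthgen",
        "seed": cfg.seed,
    }
    if c.cell_id is not None:
        meta["cell_id"] = c.cell_id
    curve = ForceCurve(np.column_stack([pos_app, f_app]), np.column_stack([pos_ret, f_ret]), meta)
    dip_area_pn_nm = 0.5 * c.dip_depth_pn * c.dip_width_nm
    truth = GroundTruth(
        "force_curve",
        {
            "contact_nm": c.contact_nm,
            "slope_pn_per_nm": c.slope_pn_per_nm,
            "dip_depth_pn": c.dip_depth_pn,
            "dip_width_nm": c.dip_width_nm,
            "dip_area_pn_nm": dip_area_pn_nm,
            "adhesion_energy_J": dip_area_pn_nm * PN_NM_TO_J,
            "baseline_pn": c.baseline_pn,
            "baseline_tilt_pn_per_nm": c.baseline_tilt_pn_per_nm,
            "noise_sd_pn": c.noise_sd_pn,
            "cell_id": c.cell_id,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# spot images


def _sample_centers(spec: SpotSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    margin = spec.margin_px if spec.margin_px is not None else 3.0 * spec.sigma_px
    rows, cols = shape
    lo_r, hi_r = margin, rows - 1 - margin
    lo_c, hi_c = margin, cols - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("image too small for requested spot margin")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < spec.n_spots:
        attempts += 1
        if attempts > 10000 * max(1, spec.n_spots):
            raise ValueError(
                f"could not place {spec.n_spots} spots with minimum separation "
                f"{spec.min_separation_px} px in a {rows}x{cols} image"
            )
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(math.dist(cand, c) >= spec.min_separation_px for c in centers):
            centers.append(cand)
    return np.asarray(centers)


def make_spot_image(cfg: SynthConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate a 16-bit grayscale image of Gaussian spots on a flat
    background with optional Poisson shot noise and Gaussian read noise."""
    spec = cfg.spot
    rows, cols = cfg.image_shape
    rng = cfg.rng("spot_image")
    if spec.centers is not None:
        centers = np.asarray(spec.centers, dtype=float).reshape(-1, 2)
        if centers.shape[0] != spec.n_spots:
            raise ValueError("explicit centers must match n_spots")
    else:
        centers = _sample_centers(spec, (rows, cols), rng)

    yy = np.arange(rows)[:, None]
    xx = np.arange(cols)[None, :]
    signal = np.full((rows, cols), float(spec.background))
    for cy, cx in centers:
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        signal += spec.amplitude * np.exp(-r2 / (2.0 * spec.sigma_px**2))

    noisy = signal
    if spec.poisson:
        noisy = rng.poisson(np.maximum(signal, 0.0)).astype(float)
    if spec.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.read_noise_sd, (rows, cols))
    image = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    pairs = []
    if centers.shape[0] >= 2 and centers.shape[0] <= 50:
        for i in range(centers.shape[0]):
            for j in range(i + 1, centers.shape[0]):
                sep = float(math.dist(centers[i], centers[j]))
                pairs.append(
                    {
                        "pair": (i, j),
                        "separation_px": sep,
                        "resolvable": sep > RESOLVABLE_SEPARATION_SIGMA * spec.sigma_px,
                    }
                )
    truth = GroundTruth(
        "spot_image",
        {
            "n_spots": int(centers.shape[0]),
            "centers": centers.tolist(),
            "sigma_px": spec.sigma_px,
            "amplitude": spec.amplitude,
            "background": spec.background,
            "pixel_size_um": cfg.pixel_size_um,
            "pairs": pairs,
        },
    )
    return image, truth


# ---------------------------------------------------------------------------
# fluorescent fibers


def _dist_to_segment(py: np.ndarray, px_: np.ndarray, p0: tuple[float, float], p1: tuple[float, float]) -> np.ndarray:
    ay, ax = p0
    by, bx = p1
    vy, vx = by - ay, bx - ax
    vv = vy * vy + vx * vx
    if vv == 0:
        return np.hypot(py - ay, px_ - ax)
    t = np.clip(((py - ay) * vy + (px_ - ax) * vx) / vv, 0.0, 1.0)
    return np.hypot(py - (ay + t * vy), px_ - (ax + t * vx))


def make_fiber_image(cfg: SynthConfig) -> tuple[np.ndarray, GroundTruth]:
    """Generate a fluorescence image of straight fibers with Gaussian
    cross-sections (for diameter/length morphometry)."""
    rows, cols = cfg.image_shape
    px = cfg.pixel_size_um
    yy = np.arange(rows)[:, None] * px
    xx = np.arange(cols)[None, :] * px
    img = np.zeros((rows, cols))
    for f in cfg.fluor_fibers:
        d = _dist_to_segment(yy, xx, f.p0_um, f.p1_um)
        img += f.amplitude * np.exp(-(d**2) / (2.0 * f.sigma_um**2))
    if cfg.noise_sd > 0:
        img = img + cfg.rng("fiber_image").normal(0.0, cfg.noise_sd, (rows, cols))
    truth = GroundTruth(
        "fiber_image",
        {
            "pixel_size_um": px,
            "fibers": [
                {**dataclasses.asdict(f), "length_um": f.length_um} for f in cfg.fluor_fibers
            ],
            "total_length_um": sum(f.length_um for f in cfg.fluor_fibers),
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# quantification tables


def make_quant_table(cfg: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a labeled quantification table.

    ``kind="protein"``: wide table (protein_id, peptides, one abundance column
    per sample) with ``n_effects`` planted log2 fold changes of size
    ``effect_log2fc`` (random sign) in the second group.

    ``kind="ct"``: tidy qPCR table (sample, group, gene, Ct) including
    housekeeping genes that track per-sample global shifts, with planted
    per-gene ΔΔCT offsets in the non-reference group.
    """
    spec = cfg.table
    if any(g < 2 for g in spec.group_sizes):
        raise ValueError("each group needs at least 2 samples")
    rng = cfg.rng("table")
    if spec.kind == "protein":
        return _make_protein_table(spec, rng)
    if spec.kind == "ct":
        return _make_ct_table(spec, rng)
    raise ValueError(f"unknown table kind {spec.kind!r}")


def _make_protein_table(spec: TableSpec, rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    n = spec.n_rows
    ga, gb = spec.group_names
    na, nb = spec.group_sizes
    ids = [f"P{i:05d}" for i in range(n)]
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, n)

    effect_idx = rng.choice(n, size=spec.n_effects, replace=False) if spec.n_effects else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=spec.n_effects)
    log2fc = np.zeros(n)
    log2fc[effect_idx] = signs * spec.effect_log2fc

    cols = {}
    sample_names = [f"{ga}_{i + 1}" for i in range(na)] + [f"{gb}_{i + 1}" for i in range(nb)]
    for s in sample_names[:na]:
        cols[s] = 2.0 ** (base + rng.normal(0.0, spec.within_sd_log2, n))
    for s in sample_names[na:]:
        cols[s] = 2.0 ** (base + log2fc + rng.normal(0.0, spec.within_sd_log2, n))

    peptides = rng.poisson(spec.peptide_lambda, n) + 1
    single = rng.random(n) < spec.frac_single_peptide
    peptides[single] = 1

    df = pd.DataFrame({"protein_id": ids, "peptides": peptides, **cols})
    design = {ga: sample_names[:na], gb: sample_names[na:]}
    truth = GroundTruth(
        "protein_table",
        {
            "design": design,
            "effect_ids": [ids[i] for i in effect_idx],
            "effect_log2fc": {ids[i]: float(log2fc[i]) for i in effect_idx},
            "within_sd_log2": spec.within_sd_log2,
        },
    )
    df.attrs["design"] = design
    return df, truth


def _make_ct_table(spec: TableSpec, rng: np.random.Generator) -> tuple[pd.DataFrame, GroundTruth]:
    ga, gb = spec.group_names
    if spec.reference_group not in (ga, gb):
        raise ValueError("reference_group must be one of group_names")
    genes = list(spec.genes)
    hks = list(spec.housekeeping)
    all_genes = genes + hks
    gene_base = {g: rng.uniform(18.0, 28.0) for g in all_genes}
    rows = []
    for group, size in zip(spec.group_names, spec.group_sizes):
        for i in range(size):
            sample = f"{group}_{i + 1}"
            shift = rng.normal(0.0, spec.sample_shift_sd)
            for g in all_genes:
                ct = gene_base[g] + shift
                if group != spec.reference_group and g in spec.planted_ddct:
                    ct += spec.planted_ddct[g]
                ct += rng.normal(0.0, spec.ct_noise_sd)
                rows.append({"sample": sample, "group": group, "gene": g, "Ct": ct})
    df = pd.DataFrame(rows)
    truth = GroundTruth(
        "ct_table",
        {
            "housekeeping": hks,
            "reference_group": spec.reference_group,
            "planted_ddct": dict(spec.planted_ddct),
            "expected_fold_change": {
                g: 2.0 ** (-d) for g, d in spec.planted_ddct.items()
            },
            "ct_noise_sd": spec.ct_noise_sd,
        },
    )
    return df, truth
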