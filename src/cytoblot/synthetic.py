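"""Synthetic single-cell populations and microwell-array immunoblot renders.

The generator emulates the statistical structure of single-cell cytoskeletal
immunoblot data: per-cell total actin follows a gamma distribution (as expected
from bursty transcription), the F-actin ratio F/(F+G) follows a normal
distribution truncated to [0, 1], and the three protein-complex readouts
(F-actin, microtubules, intermediate filaments) carry a target Spearman
rank-correlation structure induced through a Gaussian copula. Optional
subpopulations shift complex levels by a configured number of standard
deviations, planting ground-truth phenotype groups for clustering benchmarks.

``render_array`` turns a cell table into a microwell-array separation image:
one Gaussian band per probed target on each side of every occupied microwell
(monomer to the left, depolymerized complex to the right — the bi-directional
electrophoresis convention), additive Gaussian detector noise, and an optional
fraction of "dispersed" lanes whose band is replaced by a monotone smear, the
failure mode real blots show when solubilization is incomplete.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PopulationSpec",
    "SubpopSpec",
    "RenderSpec",
    "ArrayImage",
    "sample_population",
    "render_array",
    "write_image",
    "read_image",
    "CELL_COLUMNS",
]

# canonical cell-table schema (AFU columns may be NaN when not probed)
CELL_COLUMNS = [
    "cell_id",
    "condition",
    "device",
    "total_actin",
    "F",
    "G",
    "MT",
    "IF",
    "VIM_monomer",
    "f_ratio",
    "if_ratio",
    "subpop",
]

#: Spearman correlations among (F-actin, MT, IF) measured in vehicle-control
#: cells; used as the generator's default coupling.
DEFAULT_COMPLEX_CORR = np.array(
    [
        [1.00, 0.70, 0.72],
        [0.70, 1.00, 0.59],
        [0.72, 0.59, 1.00],
    ]
)


@dataclass(frozen=True)
class SubpopSpec:
    """A planted phenotype: ``fraction`` of cells shifted by ``shift`` standard
    deviations on each of (F, MT, IF)."""

    fraction: float
    shift: tuple[float, float, float]
    label: str = "subpop"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"subpop fraction must be in [0, 1], got {self.fraction}")
        if len(self.shift) != 3:
            raise ValueError("shift must give offsets for (F, MT, IF)")


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the simulated cell population.

    Defaults reproduce the study conditions: gamma(2, 5000) total actin (AFU),
    truncated-normal F-ratio with mean 0.45 and sd 0.10, truncated-normal
    IF-ratio with mean 0.63 and sd 0.11, and the control-cell rank-correlation
    structure among the three complexes.
    """

    n_cells: int = 200
    total_actin_shape: float = 2.0
    total_actin_scale: float = 5000.0
    f_ratio_mean: float = 0.45
    f_ratio_sd: float = 0.10
    if_ratio_mean: float = 0.63
    if_ratio_sd: float = 0.11
    complex_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_COMPLEX_CORR.copy()
    )
    subpops: tuple[SubpopSpec, ...] = ()
    condition: str = "control"
    device: str = "sim-1"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "complex_corr", np.asarray(self.complex_corr, float))
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.total_actin_shape <= 0 or self.total_actin_scale <= 0:
            raise ValueError("gamma parameters must be > 0")
        if not 0.0 <= self.f_ratio_mean <= 1.0:
            raise ValueError("f_ratio_mean must be in [0, 1]")
        if self.f_ratio_sd < 0:
            raise ValueError("f_ratio_sd must be >= 0")
        c = self.complex_corr
        if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("complex_corr must be a symmetric 3x3 matrix with unit diagonal")
        if sum(s.fraction for s in self.subpops) > 1.0 + 1e-12:
            raise ValueError("subpop fractions must sum to <= 1")


def _truncnorm01(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _latent_corr(spearman: np.ndarray) -> np.ndarray:
    """Pearson correlation of the latent Gaussian that yields the requested
    Spearman correlation under a Gaussian copula: r = 2 sin(pi * rho / 6)."""
    r = 2.0 * np.sin(np.pi * spearman / 6.0)
    np.fill_diagonal(r, 1.0)
    # clip to nearest PSD if rounding pushed an eigenvalue slightly negative
    w, v = np.linalg.eigh(r)
    if w.min() < 0:
        r = (v * np.clip(w, 1e-10, None)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def sample_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a cell table with the configured marginals and rank correlations.

    Total actin is gamma; F = f_ratio * total and G = total - F so the identity
    F + G = total holds exactly per cell. MT and IF are gamma with the same
    shape/scale, coupled to F through the copula; F itself is coupled by
    rank-reordering whole cells (Iman–Conover), which preserves every marginal
    and the within-cell F/G/total identity. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object if c in ("cell_id", "condition", "device", "subpop") else float) for c in CELL_COLUMNS})

    total = rng.gamma(spec.total_actin_shape, spec.total_actin_scale, size=n)
    f_ratio = _truncnorm01(spec.f_ratio_mean, spec.f_ratio_sd, n, rng)
    F = f_ratio * total
    G = total - F
    total = F + G  # bitwise-exact identity downstream

    z = rng.multivariate_normal(np.zeros(3), _latent_corr(spec.complex_corr), size=n)
    u = sps.norm.cdf(z)
    MT = sps.gamma.ppf(u[:, 1], spec.total_actin_shape, scale=spec.total_actin_scale)
    IF = sps.gamma.ppf(u[:, 2], spec.total_actin_shape, scale=spec.total_actin_scale)

    # Iman–Conover: reorder (total, ratio, F, G) rows so rank(F) matches rank(z0)
    order_by_f = np.argsort(F, kind="stable")
    rank_of_z = np.argsort(np.argsort(z[:, 0], kind="stable"), kind="stable")
    take = order_by_f[rank_of_z]
    total, f_ratio, F, G = total[take], f_ratio[take], F[take], G[take]

    if_ratio = _truncnorm01(spec.if_ratio_mean, spec.if_ratio_sd, n, rng)
    with np.errstate(divide="ignore"):
        vim = np.where(if_ratio > 0, IF * (1.0 / np.maximum(if_ratio, 1e-12) - 1.0), np.inf)

    subpop = np.array(["none"] * n, dtype=object)
    if spec.subpops:
        sds = {"F": F.std(ddof=0), "MT": MT.std(ddof=0), "IF": IF.std(ddof=0)}
        idx = rng.permutation(n)
        start = 0
        for sp in spec.subpops:
            k = int(round(sp.fraction * n))
            sel = idx[start : start + k]
            start += k
            dF, dMT, dIF = sp.shift
            F[sel] = np.maximum(F[sel] + dF * sds["F"], 0.0)
            MT[sel] = np.maximum(MT[sel] + dMT * sds["MT"], 0.0)
            IF[sel] = np.maximum(IF[sel] + dIF * sds["IF"], 0.0)
            subpop[sel] = sp.label
        total = F + G
        with np.errstate(invalid="ignore"):
            f_ratio = np.where(total > 0, F / total, np.nan)

    return pd.DataFrame(
        {
            "cell_id": [f"{spec.condition}-{i:05d}" for i in range(n)],
            "condition": spec.condition,
            "device": spec.device,
            "total_actin": total,
            "F": F,
            "G": G,
            "MT": MT,
            "IF": IF,
            "VIM_monomer": vim,
            "f_ratio": f_ratio,
            "if_ratio": if_ratio,
            "subpop": subpop,
        }
    )


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and noise of the rendered microwell-array image.

    Band defaults follow the measured separation: monomer bands centered
    350 ± 16 μm from the microwell edge with Gaussian width (σ) 66 ± 8 μm.
    ``pixel_size`` defaults to 10 μm (a typical microarray-scanner setting).
    """

    pixel_size: float = 10.0
    lane_length: float = 700.0
    lane_pitch: float = 160.0
    lane_width: float = 40.0
    microwell_halfwidth: float = 30.0
    peak_center_mean: float = 350.0
    peak_center_sd: float = 16.0
    peak_width_mean: float = 66.0
    peak_width_sd: float = 8.0
    baseline: float = 100.0
    noise_sd: float = 5.0
    bit_depth: int = 16
    dispersed_fraction: float = 0.0
    grid: tuple[int, int] = (10, 6)

    def __post_init__(self) -> None:
        for name in ("pixel_size", "lane_length", "lane_pitch", "lane_width", "microwell_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.dispersed_fraction <= 1.0:
            raise ValueError("dispersed_fraction must be in [0, 1]")
        if self.peak_center_mean + 2.0 * self.peak_width_mean >= self.lane_length:
            raise ValueError("band (center + 2 widths) must fit inside the lane")

    @property
    def capacity(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class ArrayImage:
    """A separation-array image: intensity grid plus the geometry needed to
    segment it (microwell centers in pixels, lane extents in μm)."""

    intensities: np.ndarray  # float AFU, clipped to [0, 2**bit_depth - 1]
    pixel_size: float
    well_centers: list[tuple[int, int]]  # (row_px, col_px) per microwell
    lane_length: float
    lane_width: float
    microwell_halfwidth: float

    def geometry_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size,
            "well_centers_px": [list(c) for c in self.well_centers],
            "lane_length_um": self.lane_length,
            "lane_width_um": self.lane_width,
            "microwell_halfwidth_um": self.microwell_halfwidth,
        }

    @classmethod
    def from_arrays(cls, intensities: np.ndarray, geometry: dict) -> "ArrayImage":
        return cls(
            intensities=np.asarray(intensities, float),
            pixel_size=float(geometry["pixel_size_um"]),
            well_centers=[tuple(c) for c in geometry["well_centers_px"]],
            lane_length=float(geometry["lane_length_um"]),
            lane_width=float(geometry["lane_width_um"]),
            microwell_halfwidth=float(geometry["microwell_halfwidth_um"]),
        )


def render_array(
    cells: pd.DataFrame,
    render: RenderSpec,
    seed: int,
    targets: tuple[tuple[str, str], ...] = (("G", "monomer"), ("F", "complex")),
) -> tuple[ArrayImage, pd.DataFrame]:
    """Render one image channel with a band per (column, side) for every cell.

    ``targets`` maps cell-table columns to lane sides; the default is the actin
    probe (G-actin monomer left, F-actin complex right). Band area on the
    profile equals the cell's AFU value exactly (amplitude = AUC / (σ√2π)).
    Returns the image and a ground-truth table with one row per rendered band.
    """
    n = len(cells)
    if n > render.capacity:
        raise ValueError(f"{n} cells exceed grid capacity {render.capacity}")
    rng = np.random.default_rng(seed)
    rows, cols = render.grid
    px = render.pixel_size

    margin_um = 40.0
    unit_w_um = 2.0 * (render.microwell_halfwidth + render.lane_length) + margin_um
    width_px = int(np.ceil(cols * unit_w_um / px))
    height_px = int(np.ceil(rows * render.lane_pitch / px))
    img = np.full((height_px, width_px), render.baseline, dtype=float)

    well_centers: list[tuple[int, int]] = []
    truth_rows: list[dict] = []
    x_px = np.arange(width_px) * px  # μm at pixel centers

    half_lane_px = max(1, int(round(render.lane_width / 2.0 / px)))
    cell_iter = cells.reset_index(drop=True)

    for idx in range(render.capacity):
        r, c = divmod(idx, cols)
        cx_um = c * unit_w_um + margin_um / 2.0 + render.microwell_halfwidth + render.lane_length
        cy_um = (r + 0.5) * render.lane_pitch
        cx, cy = int(round(cx_um / px)), int(round(cy_um / px))
        well_centers.append((cy, cx))

        y0, y1 = cy - half_lane_px, cy + half_lane_px  # lane rows (transverse)
        # microwell rendered dark
        wpx = max(1, int(round(render.microwell_halfwidth / px)))
        img[y0 : y1 + 1, max(cx - wpx, 0) : cx + wpx + 1] = 0.0

        if idx >= n:
            truth_rows.append(
                dict(lane_id=idx, cell_id=None, row=r, col=c, target=None, side=None,
                     true_auc=np.nan, center_um=np.nan, sigma_um=np.nan, lane_class="empty")
            )
            continue

        cell = cell_iter.iloc[idx]
        dispersed = rng.random() < render.dispersed_fraction
        lane_class = "dispersed" if dispersed else "clean"
        for col_name, side in targets:
            auc = float(cell[col_name])
            sign = -1.0 if side == "monomer" else 1.0
            edge_um = cx_um + sign * render.microwell_halfwidth
            center = rng.normal(render.peak_center_mean, render.peak_center_sd)
            sigma = max(rng.normal(render.peak_width_mean, render.peak_width_sd), 5.0)
            d_um = sign * (x_px - edge_um)  # distance from microwell edge, along lane
            in_lane = (d_um > 0) & (d_um <= render.lane_length)
            if dispersed:
                lam = render.lane_length / 3.0
                norm = lam * (1.0 - np.exp(-render.lane_length / lam))
                prof = np.where(in_lane, auc / norm * np.exp(-np.clip(d_um, 0, None) / lam), 0.0)
            else:
                amp = auc / (sigma * np.sqrt(2.0 * np.pi))
                prof = np.where(in_lane, amp * np.exp(-((d_um - center) ** 2) / (2.0 * sigma**2)), 0.0)
            img[y0 : y1 + 1, :] += prof[None, :]
            truth_rows.append(
                dict(lane_id=idx, cell_id=cell["cell_id"], row=r, col=c, target=col_name,
                     side=side, true_auc=auc, center_um=center, sigma_um=sigma,
                     lane_class=lane_class)
            )

    if render.noise_sd > 0:
        img += rng.normal(0.0, render.noise_sd, size=img.shape)
    np.clip(img, 0.0, 2.0**render.bit_depth - 1.0, out=img)

    image = ArrayImage(
        intensities=img,
        pixel_size=px,
        well_centers=well_centers,
        lane_length=render.lane_length,
        lane_width=render.lane_width,
        microwell_halfwidth=render.microwell_halfwidth,
    )
    return image, pd.DataFrame(truth_rows)


def write_image(image: ArrayImage, tiff_path, geometry_path) -> None:
    """Write the image as 16-bit grayscale TIFF plus a geometry JSON."""
    import tifffile

    arr = np.clip(np.round(image.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(tiff_path), arr)
    with open(geometry_path, "w") as fh:
        json.dump(image.geometry_dict(), fh, indent=2)


def read_image(tiff_path, geometry_path) -> ArrayImage:
    import tifffile

    with open(geometry_path) as fh:
        geom = json.load(fh)
    return ArrayImage.from_arrays(tifffile.imread(str(tiff_path)).astype(float), geom)


def spec_to_json(spec) -> dict:
    """Round-trip helper: dataclass spec -> plain dict."""
    d = dataclasses.asdict(spec)
    if "complex_corr" in d:
        d["complex_corr"] = np.asarray(d["complex_corr"]).tolist()
    return d


def population_spec_from_json(d: dict) -> PopulationSpec:
    d = dict(d)
    if "subpops" in d:
        d["subpops"] = tuple(
            SubpopSpec(**s) if isinstance(s, dict) else s for s in d["subpops"]
        )
    return PopulationSpec(**d)


def render_spec_from_json(d: dict) -> RenderSpec:
    d = dict(d)
    if "grid" in d:
        d["grid"] = tuple(d["grid"])
    return RenderSpec(**d)
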