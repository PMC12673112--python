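"""Synthetic zonated-tissue generator.

Emulates the statistical world the turnover-score method assumes:

* a zonated epithelium (default 6 zones, crypt/villus base to tip), each
  zone a multinomial gene program in which every gene peaks in one zone
  with a Gaussian profile along the axis;
* tip-biased shedding: zone z sheds at a relative rate ``gradient**z``, so
  the wash (shed-cell) bulk over-represents top zones while the biopsy
  bulk mixes zones by tissue abundance;
* single cells and single shed cells drawn multinomially from zone
  programs at realistic UMI depths;
* a spatial pixel grid of repeating crypt units with epithelial, lamina
  propria and muscularis compartments, a designated high-shedding subset
  of the inter-crypt surface, and a microenvironment gene program spiked
  in lamina pixels near the high-shedding pixels.

Counts are multinomial given a mixture; bulk samples optionally receive
Dirichlet sample-level overdispersion. Every output is a pure function of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import CountMatrix, ParameterError

DEFAULT_N_ZONES = 6
DEFAULT_N_GENES = 1000
DEFAULT_SHARPNESS = 1.0
DEFAULT_SHEDDING_GRADIENT = 2.0
DEFAULT_CELL_DEPTH_MEAN = 4000
DEFAULT_CELL_DEPTH_SIGMA = 0.3
DEFAULT_BULK_READS = 1_000_000
DEFAULT_DIRICHLET_CONCENTRATION = 1e4
DEFAULT_PIXEL_PITCH_UM = 8.0
DEFAULT_PIXEL_DEPTH_MEAN = 300
DEFAULT_PIXEL_DEPTH_SIGMA = 0.4


@dataclass
class SyntheticTruth:
    """Ground truth for a zonated epithelium simulation.

    ``zone_programs``: zones x genes, each row a probability vector.
    ``abundance``: per-zone fraction of tissue cells (sums to 1).
    ``shedding``: per-zone relative shedding propensity (> 0).
    ``stroma_programs``: programs for non-epithelial compartments
    (lamina_propria, muscularis), used only by the spatial grid.
    """

    zone_programs: pd.DataFrame
    abundance: np.ndarray
    shedding: np.ndarray
    stroma_programs: pd.DataFrame
    seed: int
    spiked_genes: dict[str, list[str]] = field(default_factory=dict)
    # continuous-axis parameters behind the binned zone programs; None for
    # hand-built truths, in which case cells sample the bin programs
    gene_peaks: np.ndarray | None = None
    gene_magnitude: np.ndarray | None = None
    zonation_sharpness: float | None = None

    def __post_init__(self) -> None:
        rows = self.zone_programs.to_numpy()
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("zone programs must each sum to 1")
        if not np.isclose(self.abundance.sum(), 1.0):
            raise ParameterError("zone abundances must sum to 1")
        if (self.shedding <= 0).any():
            raise ParameterError("shedding propensities must be > 0")
        if len(self.abundance) != len(self.zone_programs):
            raise ParameterError("abundance/zone dimension mismatch")

    @property
    def n_zones(self) -> int:
        return len(self.zone_programs)

    @property
    def genes(self) -> pd.Index:
        return self.zone_programs.columns

    def biopsy_mixture(self) -> np.ndarray:
        """Expected tissue (biopsy) gene mixture: abundance-weighted."""
        return self.abundance @ self.zone_programs.to_numpy()

    def wash_mixture(self) -> np.ndarray:
        """Expected shed-cell (wash) gene mixture: shedding-biased."""
        w = self.abundance * self.shedding
        w = w / w.sum()
        return w @ self.zone_programs.to_numpy()

    def shed_zone_probs(self) -> np.ndarray:
        w = self.abundance * self.shedding
        return w / w.sum()

    def program_at(self, positions: np.ndarray) -> np.ndarray:
        """Gene programs at continuous crypt-axis positions.

        Zone z corresponds to position z; a cell's position varies
        continuously within its zone bin [z - 0.5, z + 0.5]. Falls back to
        the binned programs when the truth has no continuous parameters
        (hand-built truths).
        """
        positions = np.asarray(positions, dtype=float)
        if self.gene_peaks is None:
            bins = np.clip(np.round(positions).astype(int), 0,
                           self.n_zones - 1)
            return self.zone_programs.to_numpy()[bins]
        w = self.gene_magnitude[None, :] * np.exp(
            -((positions[:, None] - self.gene_peaks[None, :]) ** 2)
            / (2 * self.zonation_sharpness ** 2))
        return w / w.sum(axis=1, keepdims=True)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": int(self.seed),
            "n_zones": int(self.n_zones),
            "abundance": [float(a) for a in self.abundance],
            "shedding": [float(s) for s in self.shedding],
            "spiked_genes": {k: list(v) for k, v in self.spiked_genes.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc))


def make_zonated_truth(n_zones: int = DEFAULT_N_ZONES,
                       n_genes: int = DEFAULT_N_GENES,
                       zonation_sharpness: float = DEFAULT_SHARPNESS,
                       shedding_gradient: float = DEFAULT_SHEDDING_GRADIENT,
                       seed: int = 0,
                       abundance: Sequence[float] | None = None,
                       ) -> SyntheticTruth:
    """Build a zonated ground truth.

    Each gene gets a peak position uniform along the zone axis and a
    log-normal magnitude; its weight in zone z falls off as a Gaussian of
    width ``zonation_sharpness`` (in zone units) around the peak. Shedding
    propensity of zone z is ``shedding_gradient**z`` (gradient 1 = the
    null design where every zone sheds equally).
    """
    if n_zones < 2:
        raise ParameterError("need at least 2 zones")
    if n_genes < 10:
        raise ParameterError("need at least 10 genes")
    if shedding_gradient <= 0:
        raise ParameterError("shedding_gradient must be > 0")
    if zonation_sharpness <= 0:
        raise ParameterError("zonation_sharpness must be > 0")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)])
    peaks = rng.uniform(-0.5, n_zones - 0.5, size=n_genes)
    magnitude = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    z = np.arange(n_zones)[:, None]
    weights = magnitude[None, :] * np.exp(
        -((z - peaks[None, :]) ** 2) / (2 * zonation_sharpness ** 2))
    programs = weights / weights.sum(axis=1, keepdims=True)
    zone_programs = pd.DataFrame(
        programs, index=[f"V{i + 1}" for i in range(n_zones)], columns=genes)

    # stromal compartments: own random log-normal programs over the same
    # gene universe, independent of the zonation axis
    stroma = {}
    for name in ("lamina_propria", "muscularis"):
        mag = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
        stroma[name] = mag / mag.sum()
    stroma_programs = pd.DataFrame(stroma, index=genes).T

    if abundance is None:
        abund = np.full(n_zones, 1.0 / n_zones)
    else:
        abund = np.asarray(abundance, dtype=float)
        abund = abund / abund.sum()
    shedding = shedding_gradient ** np.arange(n_zones, dtype=float)
    return SyntheticTruth(zone_programs, abund, shedding, stroma_programs,
                          seed=seed, gene_peaks=peaks,
                          gene_magnitude=magnitude,
                          zonation_sharpness=zonation_sharpness)


def with_spike(truth: SyntheticTruth, genes: Sequence[str], fold: float,
               zones: Sequence[str] | None = None,
               label: str = "spike") -> SyntheticTruth:
    """Return a new truth with ``genes`` multiplied by ``fold`` (then
    renormalized) in the programs of ``zones`` (default: all zones)."""
    progs = truth.zone_programs.copy()
    rows = progs.index if zones is None else pd.Index(zones)
    missing = pd.Index(genes).difference(progs.columns)
    if len(missing):
        raise ParameterError(f"unknown spike genes: {list(missing[:5])}")
    for row in rows:
        v = progs.loc[row].to_numpy().copy()
        idx = progs.columns.get_indexer(genes)
        v[idx] *= fold
        progs.loc[row] = v / v.sum()
    spiked = dict(truth.spiked_genes)
    spiked[label] = list(genes)
    # a zone-specific multiplicative spike has no continuous-axis
    # representation; spiked truths therefore sample the binned programs
    return replace(truth, zone_programs=progs, spiked_genes=spiked,
                   gene_peaks=None, gene_magnitude=None,
                   zonation_sharpness=None)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _draw_depths(rng, n, mean, sigma, floor=50):
    d = rng.lognormal(mean=np.log(mean), sigma=sigma, size=n)
    return np.maximum(np.round(d).astype(int), floor)


def _multinomial_rows(rng, depths, probs_per_row):
    out = np.empty((len(depths), probs_per_row.shape[1]), dtype=np.int64)
    for i, (d, p) in enumerate(zip(depths, probs_per_row)):
        out[i] = rng.multinomial(d, p)
    return out


def simulate_cells(truth: SyntheticTruth, n_cells: int = 3000,
                   depth_mean: float = DEFAULT_CELL_DEPTH_MEAN,
                   depth_sigma: float = DEFAULT_CELL_DEPTH_SIGMA,
                   seed: int = 0,
                   zone_probs: Sequence[float] | None = None,
                   obs_prefix: str = "cell",
                   ) -> CountMatrix:
    """Draw single cells along the continuous crypt axis.

    Each cell draws a zone from the tissue abundances (or ``zone_probs``),
    a continuous position uniform within that zone's bin, a log-normal UMI
    depth, then multinomial gene counts from the program at its position.
    The continuous position models real within-zone heterogeneity: zones
    are bins of a continuous maturation axis, so score distributions per
    zone overlap as they do in tissue. Zone labels land in
    ``obs_meta['zone']`` (0-based), ``obs_meta['group']`` (zone name) and
    ``obs_meta['position']``. Hand-built or spiked truths without
    continuous parameters sample the binned zone programs instead.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    probs = truth.abundance if zone_probs is None else np.asarray(zone_probs)
    probs = probs / probs.sum()
    zones = rng.choice(truth.n_zones, size=n_cells, p=probs)
    positions = zones + rng.uniform(-0.5, 0.5, size=n_cells)
    depths = _draw_depths(rng, n_cells, depth_mean, depth_sigma)
    counts = _multinomial_rows(rng, depths, truth.program_at(positions))
    obs = pd.Index([f"{obs_prefix}{i:05d}" for i in range(n_cells)])
    values = pd.DataFrame(counts.T, index=truth.genes, columns=obs)
    meta = pd.DataFrame({
        "role": "cell",
        "zone": zones,
        "position": positions,
        "group": truth.zone_programs.index.to_numpy()[zones],
    }, index=obs)
    return CountMatrix(values, meta)


def simulate_wash_biopsy(truth: SyntheticTruth, n_wash_samples: int = 3,
                         n_biopsy_samples: int = 3,
                         reads_per_sample: int = DEFAULT_BULK_READS,
                         dirichlet_concentration: float | None =
                         DEFAULT_DIRICHLET_CONCENTRATION,
                         seed: int = 0) -> CountMatrix:
    """Paired wash/biopsy bulk samples.

    The biopsy mixture weights zones by tissue abundance; the wash mixture
    weights them by abundance x shedding. Each sample's mixture is
    perturbed by a Dirichlet draw with concentration
    ``dirichlet_concentration * mixture`` (None disables the sample-level
    noise), then counts are multinomial at ``reads_per_sample``.
    """
    rng = np.random.default_rng(seed)
    cols, mats, roles = [], [], []
    for role, mix, n in (("wash", truth.wash_mixture(), n_wash_samples),
                         ("biopsy", truth.biopsy_mixture(),
                          n_biopsy_samples)):
        for i in range(n):
            p = mix
            if dirichlet_concentration is not None:
                alpha = np.maximum(dirichlet_concentration * mix, 1e-8)
                p = rng.dirichlet(alpha)
            mats.append(rng.multinomial(int(reads_per_sample), p))
            cols.append(f"{role}{i + 1}")
            roles.append(role)
    values = pd.DataFrame(np.array(mats).T, index=truth.genes,
                          columns=pd.Index(cols))
    meta = pd.DataFrame({"role": roles}, index=values.columns)
    return CountMatrix(values, meta)


def simulate_shed_cells(truth: SyntheticTruth, n_cells: int = 300,
                        depth_mean: float = DEFAULT_CELL_DEPTH_MEAN,
                        depth_sigma: float = DEFAULT_CELL_DEPTH_SIGMA,
                        seed: int = 0,
                        apoptosis_genes: Sequence[str] | None = None,
                        apoptosis_fold: float = 1.0) -> CountMatrix:
    """Single shed cells: zones drawn with probability proportional to
    abundance x shedding. An optional apoptosis-program spike multiplies
    ``apoptosis_genes`` by ``apoptosis_fold`` in every zone program before
    sampling (fold 1 = off)."""
    t = truth
    if apoptosis_genes is not None and apoptosis_fold != 1.0:
        t = with_spike(truth, apoptosis_genes, apoptosis_fold,
                       label="apoptosis")
    m = simulate_cells(t, n_cells=n_cells, depth_mean=depth_mean,
                       depth_sigma=depth_sigma, seed=seed,
                       zone_probs=truth.shed_zone_probs(),
                       obs_prefix="shed")
    m.obs_meta["shed"] = True
    return m


# ---------------------------------------------------------------------------
# Spatial grid
# ---------------------------------------------------------------------------

@dataclass
class GridLayout:
    """Geometry of the repeating crypt units (all sizes in pixels)."""

    n_units: int = 12
    unit_width: int = 12
    crypt_width: int = 4
    crypt_depth: int = 10
    surface_rows: int = 2
    lamina_rows: int = 8
    muscularis_rows: int = 3


def simulate_spatial_grid(truth: SyntheticTruth,
                          layout: GridLayout | None = None,
                          pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
                          depth_mean: float = DEFAULT_PIXEL_DEPTH_MEAN,
                          depth_sigma: float = DEFAULT_PIXEL_DEPTH_SIGMA,
                          microenv_genes: Sequence[str] | None = None,
                          microenv_fold: float = 3.0,
                          microenv_radius_um: float = 70.0,
                          high_shedding_fraction: float = 0.02,
                          seed: int = 0) -> CountMatrix:
    """Lay out a pixel lattice of repeating crypt units and sample counts.

    Compartments (``obs_meta['compartment']``): ``inter_crypt`` surface
    epithelium (top ``surface_rows`` rows outside crypt mouths),
    ``crypt_wall`` and ``crypt_bottom`` (the central ``crypt_width``
    columns of each unit, descending ``crypt_depth`` rows),
    ``lamina_propria`` (between and beneath crypts) and ``muscularis``
    (bottom band). Epithelial pixels draw from the zone program matching
    their position along the crypt axis: the crypt bottom is zone 0 and
    the surface the top zone. A random ``high_shedding_fraction`` of
    inter-crypt pixels is designated high-shedding
    (``obs_meta['high_shedding']``) and draws from the top-zone program,
    while the remaining inter-crypt pixels draw from the next zone down.
    Lamina pixels within ``microenv_radius_um`` of a high-shedding pixel
    receive the microenvironment spike (``microenv_genes`` x
    ``microenv_fold``; marked ``obs_meta['microenv_spiked']``).
    """
    layout = layout or GridLayout()
    if layout.crypt_depth + layout.lamina_rows + layout.muscularis_rows < 3 \
            or layout.n_units < 1 or layout.unit_width <= layout.crypt_width:
        raise ParameterError("grid geometry too small for one crypt unit")
    rng = np.random.default_rng(seed)
    n_zones = truth.n_zones
    width = layout.n_units * layout.unit_width
    height = layout.crypt_depth + layout.lamina_rows + layout.muscularis_rows

    margin = (layout.unit_width - layout.crypt_width) // 2
    records = []
    for row in range(height):
        for col in range(width):
            in_unit = col % layout.unit_width
            in_crypt_cols = margin <= in_unit < margin + layout.crypt_width
            if row >= height - layout.muscularis_rows:
                comp, zone = "muscularis", -1
            elif row < layout.crypt_depth and in_crypt_cols:
                if row == layout.crypt_depth - 1:
                    comp, zone = "crypt_bottom", 0
                else:
                    # deeper rows map to lower zones; surface-adjacent wall
                    # rows approach (but stay below) the top zone
                    frac = 1.0 - row / max(layout.crypt_depth - 1, 1)
                    comp = "crypt_wall"
                    zone = min(int(round(frac * (n_zones - 2))), n_zones - 2)
            elif row < layout.surface_rows:
                comp, zone = "inter_crypt", n_zones - 2
            else:
                comp, zone = "lamina_propria", -1
            records.append((row, col, comp, zone))
    meta = pd.DataFrame(records, columns=["row", "col", "compartment",
                                          "zone"])
    meta.index = pd.Index([f"px{r:03d}_{c:03d}" for r, c
                           in zip(meta["row"], meta["col"])])
    meta["x_um"] = meta["col"] * pixel_pitch_um
    meta["y_um"] = meta["row"] * pixel_pitch_um
    meta["role"] = "pixel"

    ic = meta.index[meta["compartment"] == "inter_crypt"]
    n_high = max(int(round(high_shedding_fraction * len(ic))), 1)
    high_px = pd.Index(rng.choice(ic, size=n_high, replace=False))
    meta["high_shedding"] = meta.index.isin(high_px)
    meta.loc[high_px, "zone"] = n_zones - 1

    # microenvironment spike near high-shedding pixels
    lam = meta.index[meta["compartment"] == "lamina_propria"]
    lam_xy = meta.loc[lam, ["x_um", "y_um"]].to_numpy()
    high_xy = meta.loc[high_px, ["x_um", "y_um"]].to_numpy()
    d2 = ((lam_xy[:, None, :] - high_xy[None, :, :]) ** 2).sum(axis=2)
    near = (d2 <= microenv_radius_um ** 2 * (1 + 1e-12)).any(axis=1)
    spiked_px = lam[near]
    meta["microenv_spiked"] = meta.index.isin(spiked_px)

    if microenv_genes is None and microenv_fold != 1.0:
        # default: 20 genes drawn from the best-expressed lamina genes so a
        # 3x spike is detectable at pixel depth
        lam_prog = truth.stroma_programs.loc["lamina_propria"]
        top = lam_prog.sort_values(ascending=False).index[:200]
        microenv_genes = list(rng.choice(top, size=20, replace=False))
    microenv_genes = list(microenv_genes or [])

    programs = truth.zone_programs.to_numpy()
    lam_base = truth.stroma_programs.loc["lamina_propria"].to_numpy()
    mus_prog = truth.stroma_programs.loc["muscularis"].to_numpy()
    lam_spiked = lam_base.copy()
    if microenv_genes and microenv_fold != 1.0:
        idx = truth.genes.get_indexer(microenv_genes)
        lam_spiked[idx] *= microenv_fold
        lam_spiked = lam_spiked / lam_spiked.sum()

    prob_rows = np.empty((len(meta), len(truth.genes)))
    comp = meta["compartment"].to_numpy()
    zone = meta["zone"].to_numpy()
    spk = meta["microenv_spiked"].to_numpy()
    epith = np.isin(comp, ("crypt_bottom", "crypt_wall", "inter_crypt"))
    prob_rows[epith] = programs[zone[epith]]
    prob_rows[comp == "muscularis"] = mus_prog
    lam_mask = comp == "lamina_propria"
    prob_rows[lam_mask & ~spk] = lam_base
    prob_rows[lam_mask & spk] = lam_spiked

    depths = _draw_depths(rng, len(meta), depth_mean, depth_sigma)
    counts = _multinomial_rows(rng, depths, prob_rows)
    values = pd.DataFrame(counts.T, index=truth.genes, columns=meta.index)
    out = CountMatrix(values, meta)
    out.obs_meta["group"] = meta["compartment"]
    # record the spiked gene set on the matrix for downstream tests/reports
    out.microenv_genes = microenv_genes
    return out
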