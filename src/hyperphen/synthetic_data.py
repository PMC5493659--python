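"""Synthetic inputs for every pipeline stage, with stored ground truth.

Two generators are provided:

* :func:`simulate_cube` emits a raw binary acquisition stream plus dark and
  white calibration frames whose calibrated reflectance is a known,
  parametric vegetation spectrum on a known plant mask over a flat dark
  background.  The plant spectrum is the sum of a Gaussian green peak, a
  Gaussian chlorophyll absorption feature near 680 nm, and a logistic red
  edge rising to a near-infrared plateau; a latent chlorophyll variable
  deepens the absorption and shifts the red-edge inflection (700-720 nm),
  and a latent biomass variable scales the NIR plateau and the plant's
  projected area.  This is a deliberately simple shape model, not a
  radiative-transfer simulation.

* :func:`simulate_population` draws a biallelic SNP panel and a pair of
  phenotypes under a bivariate additive model: correlated per-SNP effects
  (optionally with a handful of large-effect QTLs) give genetic values that
  are rescaled so the realized heritabilities match the configured h2
  exactly; residuals are independent between traits.  Ground-truth genetic
  values, QTL effects and the targets (h2, r_g) are returned alongside.

All randomness flows through ``numpy.random.default_rng`` seeded from the
configuration, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cube_io import (
    CalibrationFrames,
    RawStream,
    SpectralCube,
    cube_from_stream,
    default_wavelengths,
    flatten_to_stream,
)
from .genetics import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedCube",
    "PopulationSim",
    "plant_spectrum",
    "simulate_cube",
    "simulate_population",
    "simulate_phenotyping_experiment",
    "write_vcf",
    "write_gff3",
]


@dataclass
class SimulationConfig:
    """Knobs for both the imaging and the genetic simulators.

    Imaging defaults give a 250-band cube with a clearly resolved red edge
    and per-pixel reflectance noise of 0.01; genetic defaults give a
    500-accession, 2,000-SNP panel with h2 = 0.5 for both traits and a
    genetic correlation of 0.6, the regime the estimators are validated
    in.
    """

    seed: int = 0
    # imaging
    dims: tuple[int, int] = (96, 96)       # rows x cols (width x lines)
    n_bands: int = 250
    noise_sd: float = 0.01
    background_reflectance: float = 0.25
    base_reflectance: float = 0.08
    green_peak_height: float = 0.14        # at zero chlorophyll
    red_depth_range: tuple[float, float] = (0.02, 0.065)
    red_edge_nm_range: tuple[float, float] = (700.0, 720.0)
    red_edge_slope_nm: float = 10.0
    nir_plateau_range: tuple[float, float] = (0.40, 0.65)
    plant_radius_frac: float = 0.30
    raw_dtype: str = "<u2"
    # genetics
    n_accessions: int = 500
    n_snps: int = 2000
    n_chromosomes: int = 12
    chrom_length_bp: int = 25_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1                 # SNPs per linkage block
    ld_resample: float = 0.1               # per-accession resampling rate
    n_qtl: int = 0
    qtl_share: float = 0.2                 # genetic variance through QTLs
    h2: tuple[float, float] = (0.5, 0.5)
    r_g: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2[0] <= 1.0 and 0.0 <= self.h2[1] <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if abs(self.r_g) > 1.0:
            raise ValueError("|r_g| must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")


def plant_spectrum(
    wavelengths: np.ndarray,
    chl: float,
    biomass: float,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Noise-free vegetation reflectance for latent chl, biomass in [0, 1].

    Higher chl deepens the 680-nm absorption, shifts the red-edge
    inflection toward 720 nm and damps the green peak; higher biomass
    raises the NIR plateau.
    """
    cfg = config or SimulationConfig()
    wl = np.asarray(wavelengths, dtype=float)
    green = cfg.green_peak_height * (1.0 - 0.4 * chl) * np.exp(
        -((wl - 550.0) ** 2) / (2 * 30.0**2)
    )
    d0, d1 = cfg.red_depth_range
    red_abs = (d0 + (d1 - d0) * chl) * np.exp(-((wl - 680.0) ** 2) / (2 * 16.0**2))
    e0, e1 = cfg.red_edge_nm_range
    inflection = e0 + (e1 - e0) * chl
    p0, p1 = cfg.nir_plateau_range
    plateau = p0 + (p1 - p0) * biomass
    edge = plateau / (1.0 + np.exp(-(wl - inflection) / cfg.red_edge_slope_nm))
    return np.maximum(cfg.base_reflectance + green - red_abs + edge, 0.005)


def _plant_mask(rng: np.random.Generator, rows: int, cols: int,
                radius_frac: float, biomass: float) -> np.ndarray:
    """A rosette-like blob: a central disk plus a few elliptical 'leaves'."""
    from skimage.draw import ellipse

    r0 = max(4.0, radius_frac * min(rows, cols) * (0.7 + 0.5 * biomass))
    if 2 * r0 >= min(rows, cols):
        raise ValueError(
            f"image dims {rows}x{cols} too small for plant radius {r0:.0f}"
        )
    mask = np.zeros((rows, cols), dtype=bool)
    cy, cx = rows / 2, cols / 2
    rr, cc = ellipse(cy, cx, 0.6 * r0, 0.6 * r0, shape=mask.shape)
    mask[rr, cc] = True
    for _ in range(6):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.3, 0.7) * r0
        ry = rng.uniform(0.35, 0.55) * r0
        rx = rng.uniform(0.2, 0.4) * r0
        rr, cc = ellipse(
            cy + dist * np.sin(ang), cx + dist * np.cos(ang), ry, rx,
            shape=mask.shape, rotation=rng.uniform(0, np.pi),
        )
        mask[rr, cc] = True
    return mask


@dataclass
class SimulatedCube:
    """A synthetic acquisition with its ground truth."""

    stream: RawStream
    frames: CalibrationFrames
    truth_mask: np.ndarray
    truth_plant_spectrum: np.ndarray
    truth_background_spectrum: np.ndarray
    wavelengths: np.ndarray
    chl: float
    biomass: float

    def to_cube(self, **meta) -> SpectralCube:
        """Reorganize + calibrate the emitted stream."""
        return cube_from_stream(self.stream, self.frames, self.wavelengths, **meta)


def simulate_cube(
    config: SimulationConfig,
    chl: float,
    biomass: float,
    seed: int | None = None,
) -> SimulatedCube:
    """Emit a raw stream + calibration frames for one synthetic plant.

    The reflectance scene (plant spectrum on the truth mask, flat
    background elsewhere, Gaussian noise of ``config.noise_sd``) is pushed
    backwards through the calibration equation, r = (I - dark)/(white -
    dark), to produce the raw intensities.  With an integer ``raw_dtype``
    the stream is quantized as a real sensor would; float dtypes give exact
    round-trips for zero-noise checks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.dims
    wl = default_wavelengths(config.n_bands)
    mask = _plant_mask(rng, rows, cols, config.plant_radius_frac, biomass)
    plant = plant_spectrum(wl, chl, biomass, config)
    background = np.full_like(wl, config.background_reflectance)

    refl = np.empty((config.n_bands, rows, cols))
    refl[:] = background[:, None, None]
    refl[:, mask] = plant[:, None]
    if config.noise_sd > 0:
        refl = refl + rng.normal(0.0, config.noise_sd, refl.shape)
        refl = np.maximum(refl, 0.0)

    # dark current and white reference with mild per-band structure
    band_idx = np.arange(config.n_bands)
    dark_level = 100.0 + 4.0 * np.sin(band_idx / 17.0)
    gain = 3200.0 * (0.7 + 0.3 * np.exp(-((wl - 650.0) ** 2) / (2 * 220.0**2)))
    dark = np.broadcast_to(dark_level[:, None, None], refl.shape).copy()
    white = dark + gain[:, None, None]

    raw = dark + refl * (white - dark)
    dt = np.dtype(config.raw_dtype)
    if dt.kind in "ui":
        raw = np.clip(np.rint(raw), 0, np.iinfo(dt).max)
    payload = flatten_to_stream(raw.astype(dt), "bil")
    stream = RawStream(payload, (rows, config.n_bands, cols), "bil",
                       config.raw_dtype)
    return SimulatedCube(
        stream=stream,
        frames=CalibrationFrames(dark, white),
        truth_mask=mask,
        truth_plant_spectrum=plant,
        truth_background_spectrum=background,
        wavelengths=wl,
        chl=chl,
        biomass=biomass,
    )


@dataclass
class PopulationSim:
    """A simulated mapping panel with its generative ground truth."""

    geno: GenotypeMatrix
    traits: pd.DataFrame           # accession, y1, y2
    genetic_values: np.ndarray     # n_accessions x 2
    qtl: pd.DataFrame              # snp, effect1, effect2
    true_h2: tuple[float, float]
    true_r_g: float


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> PopulationSim:
    """Draw a SNP panel and a bivariate additive phenotype pair.

    SNP dosages are binomial draws at uniform MAFs; per-SNP effect pairs
    are sampled from a bivariate normal with correlation ``r_g`` (QTL SNPs,
    if any, carry ``qtl_share`` of the genetic variance).  Genetic values
    are rescaled so the realized variance explained equals the configured
    h2 exactly; residuals are independent across traits.  Identical
    genotype rows therefore receive identical genetic values.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m, n = config.n_snps, config.n_accessions

    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(config.chrom_length_bp, size=k, replace=False)) + 1
        chroms.extend([f"chr{c:02d}"] * k)
        positions.extend(pos.tolist())
    chroms = np.array(chroms, dtype=object)
    positions = np.array(positions, dtype=np.int64)
    snp_ids = np.array(
        [f"sf{c[3:]}{p:08d}" for c, p in zip(chroms, positions)], dtype=object
    )

    freq = rng.uniform(*config.maf_range, size=m)
    if config.ld_block_size <= 1:
        dosage = rng.binomial(2, freq, size=(n, m)).astype(float)
    else:
        # linkage blocks: SNPs in a block copy a base column, with a
        # fraction of accessions independently resampled per SNP
        dosage = np.empty((n, m))
        for start in range(0, m, config.ld_block_size):
            stop = min(start + config.ld_block_size, m)
            f0 = freq[start]
            base = rng.binomial(2, f0, size=n).astype(float)
            for j in range(start, stop):
                freq[j] = f0
                col = base.copy()
                flip = rng.random(n) < config.ld_resample
                col[flip] = rng.binomial(2, f0, size=int(flip.sum()))
                dosage[:, j] = col
    geno = GenotypeMatrix(snp_ids, chroms, positions, dosage)

    h2_1, h2_2 = config.h2
    cov = np.array([[1.0, config.r_g], [config.r_g, 1.0]])
    effects = rng.multivariate_normal(np.zeros(2), cov, size=m)
    qtl_idx = np.array([], dtype=int)
    if config.n_qtl > 0:
        qtl_idx = rng.choice(m, size=config.n_qtl, replace=False)
        poly_idx = np.setdiff1d(np.arange(m), qtl_idx)
        # weight so QTLs carry qtl_share of the genetic variance
        effects[qtl_idx] *= np.sqrt(
            config.qtl_share * m / max(config.n_qtl, 1)
        )
        effects[poly_idx] *= np.sqrt(
            (1 - config.qtl_share) * m / max(len(poly_idx), 1)
        )

    sd = dosage.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(dosage)
    Z[:, ok] = (dosage[:, ok] - dosage[:, ok].mean(axis=0)) / sd[ok]
    g = Z @ effects  # n x 2

    y = np.empty((n, 2))
    for k, h2 in enumerate((h2_1, h2_2)):
        gk = g[:, k]
        if h2 > 0 and gk.std() > 0:
            gk = gk * np.sqrt(h2) / gk.std()
        else:
            gk = np.zeros(n)
        g[:, k] = gk
        e = rng.normal(size=n)
        if h2 < 1:
            e = e * np.sqrt(1 - h2) / e.std()
        else:
            e = np.zeros(n)
        y[:, k] = gk + e

    traits = pd.DataFrame(
        {"accession": geno.accessions, "y1": y[:, 0], "y2": y[:, 1]}
    )
    qtl = pd.DataFrame(
        {
            "snp": snp_ids[qtl_idx],
            "effect1": effects[qtl_idx, 0],
            "effect2": effects[qtl_idx, 1],
        }
    )
    return PopulationSim(geno, traits, g, qtl, (h2_1, h2_2), config.r_g)


#: latent (chl mean, biomass mean) per growth stage; the chl separation
#: translates into ~5 nm red-edge shifts between stages
STAGE_LATENTS = {
    "tillering": (0.75, 0.35),
    "heading": (0.50, 0.60),
    "ripening": (0.25, 0.85),
}


def simulate_phenotyping_experiment(
    n_accessions: int = 40,
    stages: tuple[str, ...] = ("tillering", "heading", "ripening"),
    config: SimulationConfig | None = None,
    seed: int = 0,
    latent_sd: float = 0.08,
):
    """An end-to-end phenotyping dataset: index table + manual trait table.

    Per accession and stage, latent chlorophyll and biomass are drawn
    around stage-specific means, a reflectance cube is generated, the
    plant segmented, and the full 1,540-index catalog extracted.  Manual
    traits are noisy affine readouts of the latents: dry weight DW (g) and
    green leaf area GLA (cm2) from biomass, SPAD-type Chl from
    chlorophyll.  Returns ``(index_table, trait_table)`` sharing
    (accession, stage) keys.
    """
    from .segmentation import segment_plant
    from .spectral_indices import assemble_index_vector, index_table

    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    vectors, trait_rows = [], []
    for stage in stages:
        chl_mu, bio_mu = STAGE_LATENTS[stage]
        for a in range(n_accessions):
            chl = float(np.clip(rng.normal(chl_mu, latent_sd), 0, 1))
            bio = float(np.clip(rng.normal(bio_mu, latent_sd), 0, 1))
            sim = simulate_cube(cfg, chl, bio,
                                seed=int(rng.integers(0, 2**31 - 1)))
            cube = sim.to_cube(stage_label=stage, accession=f"acc{a:04d}")
            mask = segment_plant(cube)
            vectors.append(assemble_index_vector(cube, mask))
            trait_rows.append(
                {
                    "accession": f"acc{a:04d}",
                    "stage": stage,
                    "DW": 4.0 + 28.0 * bio + rng.normal(0, 0.5),
                    "GLA": 150.0 + 1400.0 * bio + rng.normal(0, 25.0),
                    "Chl": 18.0 + 26.0 * chl + rng.normal(0, 0.6),
                    "chl_latent": chl,
                    "biomass_latent": bio,
                }
            )
    return index_table(vectors), pd.DataFrame(trait_rows)


# ---------------------------------------------------------------------------
# plain-text writers in the formats the pipeline consumes
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Write a panel as a minimal diploid GT-only VCF."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for c in pd.unique(geno.chrom):
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.accessions)
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j in range(geno.n_snps):
        calls = [
            gt_map.get(geno.dosage[i, j], "./.") for i in range(geno.n_accessions)
        ]
        lines.append(
            f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\tA\tG\t.\tPASS"
            f"\t.\tGT\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_gff3(
    genes: pd.DataFrame, path: str | Path
) -> Path:
    """Write a gene table (gene_id, chrom, start, end) as minimal GFF3."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for row in genes.itertuples(index=False):
        lines.append(
            f"{row.chrom}\tsynthetic\tgene\t{row.start}\t{row.end}\t.\t+\t."
            f"\tID={row.gene_id}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
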