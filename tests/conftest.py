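"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive results with plain loops
(or a different algorithm such as union-find) so they stay independent of
the library code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hyperphen import SimulationConfig, simulate_cube
from hyperphen.cube_io import SpectralCube


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_sim():
    """One simulated acquisition (80x80, default spectral parameters)."""
    return simulate_cube(SimulationConfig(seed=42, dims=(80, 80)), chl=0.6,
                         biomass=0.5)


@pytest.fixture(scope="session")
def small_cube(small_sim):
    return small_sim.to_cube()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_flat_cube(value: float, shape=(12, 6, 6), wavelengths=None) -> SpectralCube:
    """A spatially and spectrally constant cube for arithmetic checks."""
    bands = shape[0]
    if wavelengths is None:
        wavelengths = np.linspace(400, 1000, bands)
    return SpectralCube(np.full(shape, value, dtype=float), wavelengths)


def make_two_band_cube(red, nir, extra_band=0.3):
    """Cube with bands at 500/670/800 nm from per-pixel red/NIR images."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    data = np.stack([np.full_like(red, extra_band), red, nir])
    return SpectralCube(data, np.array([500.0, 670.0, 800.0]))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bil_oracle(payload_values, width, n_bands, n_lines):
    """Triple-loop unpacking of a band-interleaved-by-line sample sequence."""
    out = np.empty((n_bands, width, n_lines))
    k = 0
    for line in range(n_lines):
        for band in range(n_bands):
            for px in range(width):
                out[band, px, line] = payload_values[k]
                k += 1
    return out


def loci_oracle(chrom, pos, gap_bp):
    """Union-find single-linkage merge of positions within gap_bp."""
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if chrom[i] == chrom[j] and abs(int(pos[i]) - int(pos[j])) < gap_bp:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(
        (chrom[m[0]], min(pos[i] for i in m), max(pos[i] for i in m), len(m))
        for m in groups.values()
    )


def clump_oracle(assoc: pd.DataFrame, dosage, snp_ids, suggestive,
                 r2_max=0.25, support_p=1e-4, min_support=5):
    """Loop-based greedy LD clumping, recomputing r2 pairwise from scratch."""
    col = {s: i for i, s in enumerate(snp_ids)}
    X = np.asarray(dosage, dtype=float)
    for j in range(X.shape[1]):
        nanm = np.isnan(X[:, j])
        if nanm.any():
            X[nanm, j] = np.nanmean(X[:, j])

    def r2(a, b):
        xa, xb = X[:, col[a]], X[:, col[b]]
        if xa.std() == 0 or xb.std() == 0:
            return 0.0
        return float(np.corrcoef(xa, xb)[0, 1] ** 2)

    rows = assoc[assoc["snp"].isin(col)].copy()
    rows = rows.sort_values(["p", "chrom", "pos"], kind="mergesort")
    cand = rows[rows["p"] < suggestive]
    support = rows.loc[rows["p"] < support_p, "snp"].tolist()
    removed: set[str] = set()
    leads = []
    for _, r in cand.iterrows():
        if r["snp"] in removed:
            continue
        for _, o in cand.iterrows():
            if o["snp"] != r["snp"] and o["snp"] not in removed:
                if r2(r["snp"], o["snp"]) > r2_max:
                    removed.add(o["snp"])
        n_sup = sum(
            1 for s in support if s != r["snp"] and r2(r["snp"], s) > r2_max
        )
        if n_sup >= min_support:
            leads.append(r["snp"])
    return leads


def grm_oracle(dosage):
    """Element-by-element standardized-dosage relationship matrix."""
    X = np.asarray(dosage, dtype=float)
    n, m = X.shape
    cols = []
    for j in range(m):
        c = X[:, j]
        mu, sd = c.mean(), c.std()
        if sd > 0:
            cols.append((c - mu) / sd)
    Z = np.column_stack(cols)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.dot(Z[i], Z[j]) / Z.shape[1]
    return K
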