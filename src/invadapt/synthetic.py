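"""Synthetic inputs for the invasion-genomics pipeline.

Every downstream stage (niche overlap, distribution models, genotype-
environment association, allelic-turnover GDM, wing morphometrics) can be
exercised on data produced here, with planted ground truth recorded in
:class:`SyntheticTruth`.

The generators emulate the shape of the real study system: a stack of six
spatially autocorrelated environmental predictors (PRJ, PRS, MTP, ISO, NPP,
HF), presence-only occurrences drawn from a logistic suitability surface,
hierarchically structured biallelic SNP genotypes (three ancestries, many
small population samples, missing calls at random) with a minority of loci
whose allele frequencies follow a cline along one predictor, and 20-landmark
wing configurations with group mean-shape and size differences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

DEFAULT_LAYER_NAMES = ("PRJ", "PRS", "MTP", "ISO", "NPP", "HF")

# frequency clamp applied after cline shifts on the logit scale
FREQ_CLAMP = (0.01, 0.99)


# ---------------------------------------------------------------------------
# environmental stacks
# ---------------------------------------------------------------------------

@dataclass
class EnvStack:
    """Named raster layers on a shared grid.

    Coordinates follow the array convention: ``lon`` indexes columns and
    ``lat`` indexes rows; occurrences sampled from a stack sit at cell
    centres (integer coordinates).
    """

    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError("all layers must share one grid shape")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def as_array(self) -> np.ndarray:
        return np.stack([self.layers[n] for n in self.names])

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        return pd.DataFrame({n: self.layers[n][rows, cols] for n in self.names})

    def table(self) -> pd.DataFrame:
        """All cells as a table with ``lon``/``lat`` columns."""
        nr, nc = self.shape
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        out = pd.DataFrame({"lon": cc.ravel().astype(float), "lat": rr.ravel().astype(float)})
        for n in self.names:
            out[n] = self.layers[n].ravel()
        return out


def make_env_stack(
    n_layers: int = 6,
    grid_shape: tuple[int, int] = (100, 100),
    spatial_range: float = 8.0,
    inter_layer_correlation: np.ndarray | None = None,
    seed: int | None = None,
    names: Sequence[str] | None = None,
) -> EnvStack:
    """Spatially autocorrelated Gaussian fields with target inter-layer correlation.

    White noise is smoothed with a Gaussian kernel of width ``spatial_range``
    (cells), standardized, and mixed through the Cholesky factor of
    ``inter_layer_correlation`` so empirical correlations between layers
    approach the target as the grid grows.
    """
    nr, nc = grid_shape
    if nr < 10 or nc < 10:
        raise ValueError("grid_shape must be at least 10x10")
    if inter_layer_correlation is None:
        inter_layer_correlation = np.eye(n_layers)
    corr = np.asarray(inter_layer_correlation, dtype=float)
    if corr.shape != (n_layers, n_layers):
        raise ValueError("correlation matrix shape must be (n_layers, n_layers)")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    if np.min(np.linalg.eigvalsh(corr)) < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")
    if names is None:
        names = list(DEFAULT_LAYER_NAMES[:n_layers])
        names += [f"env{i + 1}" for i in range(len(names), n_layers)]
    if len(names) != n_layers:
        raise ValueError("need one name per layer")

    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((n_layers, nr, nc))
    for i in range(n_layers):
        fields[i] = gaussian_filter(fields[i], sigma=spatial_range, mode="reflect")
        fields[i] -= fields[i].mean()
        sd = fields[i].std()
        if sd > 0:
            fields[i] /= sd
    # PSD but possibly singular: use eigen square root instead of Cholesky
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    mixed = np.tensordot(root, fields, axes=(1, 0))
    for i in range(n_layers):
        mixed[i] -= mixed[i].mean()
        sd = mixed[i].std()
        if sd > 0:
            mixed[i] /= sd
    return EnvStack({n: mixed[i] for i, n in enumerate(names)})


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def suitability_surface(env: EnvStack, suitability_params: Mapping) -> np.ndarray:
    """Logistic suitability over the grid: expit(b0 + sum_i b_i * layer_i)."""
    eta = np.full(env.shape, float(suitability_params.get("intercept", 0.0)))
    for name, coef in suitability_params.get("coef", {}).items():
        if name not in env.layers:
            raise KeyError(f"unknown layer {name!r} in suitability_params")
        eta = eta + float(coef) * env.layers[name]
    return expit(eta)


def sample_occurrences(
    env: EnvStack,
    suitability_params: Mapping | np.ndarray,
    n: int,
    seed: int | None = None,
    region: str = "synthetic",
    year: int = 2015,
) -> pd.DataFrame:
    """Draw ``n`` presence points with cell probability proportional to suitability.

    ``suitability_params`` is either a mapping ``{"intercept": b0, "coef":
    {layer: b}}`` or a precomputed suitability grid. Points sit at cell
    centres and carry the extracted environmental values.
    """
    if isinstance(suitability_params, Mapping):
        suit = suitability_surface(env, suitability_params)
    else:
        suit = np.asarray(suitability_params, dtype=float)
        if suit.shape != env.shape:
            raise ValueError("suitability grid shape mismatch")
    if suit.min() < 0:
        raise ValueError("suitability must be non-negative")
    total = suit.sum()
    if total <= 0:
        raise ValueError("suitability surface is zero everywhere")
    rng = np.random.default_rng(seed)
    p = (suit / total).ravel()
    idx = rng.choice(p.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(idx, env.shape)
    occ = pd.DataFrame(
        {
            "lon": cols.astype(float),
            "lat": rows.astype(float),
            "region": region,
            "year": year,
        }
    )
    return pd.concat([occ, env.values_at(rows, cols)], axis=1)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x SNPs in {0,1,2} with -1 for missing, plus metadata.

    ``locus_ids`` groups SNPs into RAD loci (several SNPs can share one
    110-bp sequence); ``Q`` holds per-individual ancestry coefficients.
    Population-level environment and coordinates travel with the matrix when
    produced by the simulator.
    """

    calls: np.ndarray                      # (n_ind, n_snps) int8, -1 = missing
    individual_ids: list[str]
    populations: np.ndarray                # (n_ind,) population labels
    locus_ids: np.ndarray                  # (n_snps,) parent-locus id per SNP
    positions: np.ndarray                  # (n_snps,) position within locus
    Q: np.ndarray | None = None            # (n_ind, K)
    snp_ids: list[str] = field(default_factory=list)
    pop_env: pd.DataFrame | None = None    # per-population predictor values
    pop_coords: pd.DataFrame | None = None  # per-population lon/lat

    def __post_init__(self) -> None:
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.calls.shape[1])]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return (self.calls < 0).mean(axis=0)

    def minor_allele_count(self) -> np.ndarray:
        obs = self.calls >= 0
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        tot = 2 * obs.sum(axis=0)
        return np.minimum(alt, tot - alt)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            calls=self.calls[:, index],
            individual_ids=list(self.individual_ids),
            populations=self.populations.copy(),
            locus_ids=self.locus_ids[index],
            positions=self.positions[index],
            Q=None if self.Q is None else self.Q.copy(),
            snp_ids=[self.snp_ids[j] for j in np.atleast_1d(index)],
            pop_env=self.pop_env,
            pop_coords=self.pop_coords,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a simulated dataset."""

    causal_snp_ids: list[str] = field(default_factory=list)
    cline_predictor: str | None = None
    cline_strength: float = 0.0
    baseline_fst: float | None = None
    suitability_params: Mapping | None = None
    group_shape_effects: Mapping | None = None
    pop_ancestry: np.ndarray | None = None


def _balding_nichols(rng, p_anc: np.ndarray, fst: float, size: tuple) -> np.ndarray:
    """Beta draws around ancestral frequencies with divergence parameter fst."""
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0,1)")
    scale = (1.0 - fst) / fst
    a = np.clip(p_anc * scale, 1e-6, None)
    b = np.clip((1.0 - p_anc) * scale, 1e-6, None)
    return rng.beta(np.broadcast_to(a, size), np.broadcast_to(b, size))


def simulate_genotypes(
    n_pops: int = 90,
    n_per_pop: int = 6,
    n_snps: int = 2000,
    n_ancestries: int = 3,
    baseline_fst: float = 0.10,
    within_fst: float = 0.0,
    n_causal: int = 20,
    cline_predictor: str = "PRJ",
    cline_strength: float = 0.0,
    missing_rate: float = 0.185,
    env: EnvStack | None = None,
    mean_snps_per_locus: float = 2.0,
    seed: int | None = None,
    max_retries: int = 30,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Hierarchically structured biallelic genotypes with optional planted clines.

    Ancestral frequencies are drawn once per SNP; each of ``n_ancestries``
    genetic groups diverges from them under a Balding-Nichols model with
    parameter ``baseline_fst``. By default populations share their
    ancestry's frequency (all structure lives at the K-group level);
    ``within_fst > 0`` adds nested population-level divergence beyond what
    K latent factors can absorb. Populations sit at distinct cells of
    ``env``;
    ``n_causal`` loci get an extra logit-scale shift of ``cline_strength`` x
    the standardized value of ``cline_predictor`` at the population's cell.
    Frequencies are clamped to [0.01, 0.99] after the shift. Genotypes are
    Binomial(2, pop frequency); missingness is applied completely at random.
    Monomorphic SNPs are redrawn, with a retry cap.
    """
    if n_causal > n_snps:
        raise ValueError("n_causal cannot exceed n_snps")
    rng = np.random.default_rng(seed)
    if env is None:
        env = make_env_stack(6, (40, 40), spatial_range=5.0, seed=rng.integers(2**31))
    if cline_predictor not in env.layers:
        raise KeyError(f"cline predictor {cline_predictor!r} not in env stack")

    nr, nc = env.shape
    if n_pops > nr * nc:
        raise ValueError("more populations than raster cells")
    cells = rng.choice(nr * nc, size=n_pops, replace=False)
    prow, pcol = np.unravel_index(cells, (nr, nc))
    pop_env = env.values_at(prow, pcol)
    pop_env.index = [f"pop{i}" for i in range(n_pops)]
    pop_coords = pd.DataFrame(
        {"lon": pcol.astype(float), "lat": prow.astype(float)}, index=pop_env.index
    )
    x = pop_env[cline_predictor].to_numpy()
    zpred = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)

    # populations assigned wholly to one ancestry, round-robin so that
    # ancestry is (asymptotically) uncorrelated with the environment
    pop_anc = np.arange(n_pops) % n_ancestries
    causal = rng.choice(n_snps, size=n_causal, replace=False) if n_causal else np.array([], int)
    causal_mask = np.zeros(n_snps, bool)
    causal_mask[causal] = True

    def draw(n_draw: int) -> np.ndarray:
        """Population frequencies (n_pops x n_draw)."""
        p0 = rng.uniform(0.1, 0.9, size=n_draw)
        p_anc = _balding_nichols(rng, p0, baseline_fst, (n_ancestries, n_draw))
        if within_fst > 0:
            return _balding_nichols(rng, p_anc[pop_anc], within_fst, (n_pops, n_draw))
        return p_anc[pop_anc]

    pop_freq = draw(n_snps)
    if cline_strength != 0.0:
        shift = cline_strength * zpred[:, None]
        eta = logit(np.clip(pop_freq[:, causal_mask], 1e-9, 1 - 1e-9)) + shift
        pop_freq[:, causal_mask] = expit(eta)
    pop_freq = np.clip(pop_freq, *FREQ_CLAMP)

    n_ind = n_pops * n_per_pop
    pop_of_ind = np.repeat(np.arange(n_pops), n_per_pop)
    geno = rng.binomial(2, pop_freq[pop_of_ind]).astype(np.int8)

    # regenerate monomorphic SNPs (only possible at tiny sample sizes)
    for _ in range(max_retries):
        mono = (geno == geno[0]).all(axis=0)
        mono &= ~causal_mask  # keep planted causal draws fixed
        if not mono.any():
            break
        pop_freq[:, mono] = np.clip(draw(int(mono.sum())), *FREQ_CLAMP)
        geno[:, mono] = rng.binomial(2, pop_freq[pop_of_ind][:, mono]).astype(np.int8)
    else:
        raise RuntimeError("monomorphic SNPs persisted past the retry cap")

    if missing_rate < 0 or missing_rate >= 1:
        raise ValueError("missing_rate must be in [0,1)")
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1

    # SNPs grouped into parent RAD loci of random size
    locus_ids = np.empty(n_snps, dtype=int)
    positions = np.empty(n_snps, dtype=int)
    j = 0
    locus = 0
    while j < n_snps:
        size = int(rng.integers(1, max(2, int(round(2 * mean_snps_per_locus)))))
        size = min(size, n_snps - j)
        locus_ids[j : j + size] = locus
        positions[j : j + size] = rng.choice(110, size=size, replace=False)
        j += size
        locus += 1

    Q = np.zeros((n_ind, n_ancestries))
    Q[np.arange(n_ind), pop_anc[pop_of_ind]] = 1.0
    ids = [f"pop{p}_ind{i}" for p in range(n_pops) for i in range(n_per_pop)]
    G = GenotypeMatrix(
        calls=geno,
        individual_ids=ids,
        populations=np.array([f"pop{p}" for p in pop_of_ind]),
        locus_ids=locus_ids,
        positions=positions,
        Q=Q,
        pop_env=pop_env,
        pop_coords=pop_coords,
    )
    truth = SyntheticTruth(
        causal_snp_ids=[G.snp_ids[j] for j in causal],
        cline_predictor=cline_predictor,
        cline_strength=cline_strength,
        baseline_fst=baseline_fst,
        pop_ancestry=pop_anc,
    )
    return G, truth


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def default_wing_shape(n_landmarks: int = 20) -> np.ndarray:
    """A deterministic, non-degenerate 2-D template configuration.

    Landmarks lie on two arcs of an elongated ellipse, a crude stand-in for
    vein intersections and termini along a wing outline.
    """
    k = n_landmarks // 2
    t_top = np.linspace(0.1, np.pi - 0.1, k)
    t_bot = np.linspace(np.pi + 0.1, 2 * np.pi - 0.1, n_landmarks - k)
    t = np.concatenate([t_top, t_bot])
    pts = np.column_stack([2.0 * np.cos(t), 0.8 * np.sin(t)])
    return pts - pts.mean(axis=0)


def simulate_landmarks(
    mean_shape: np.ndarray | None = None,
    groups: Sequence[str] = ("A", "B"),
    n_per_group: int = 20,
    group_shape_effects: Mapping[str, np.ndarray] | None = None,
    size_effects: Mapping[str, float] | None = None,
    noise_sd: float = 0.01,
    size_jitter: float = 0.05,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Landmark configurations: (mean + group effect + isotropic noise),
    scaled by per-individual size and placed at random orientation/position.

    Returns ``(configs, factors)`` with configs of shape
    (n_individuals, n_landmarks, 2) and a factor table with a ``group``
    column and alternating ``sex`` labels.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if mean_shape is None:
        mean_shape = default_wing_shape()
    mean_shape = np.asarray(mean_shape, dtype=float)
    centred = mean_shape - mean_shape.mean(axis=0)
    if np.sqrt((centred**2).sum()) <= 0:
        raise ValueError("mean_shape is degenerate (zero centroid size)")
    group_shape_effects = group_shape_effects or {}
    size_effects = size_effects or {}
    rng = np.random.default_rng(seed)

    configs, rows = [], []
    for g in groups:
        eff = np.asarray(group_shape_effects.get(g, 0.0), dtype=float)
        base = mean_shape + eff
        scale0 = float(size_effects.get(g, 1.0))
        for i in range(n_per_group):
            cfg = base + rng.normal(0.0, noise_sd, size=mean_shape.shape)
            s = scale0 * np.exp(rng.normal(0.0, size_jitter)) if size_jitter > 0 else scale0
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            cfg = s * cfg @ R.T + rng.uniform(-5, 5, size=2)
            configs.append(cfg)
            rows.append({"id": f"{g}_{i}", "group": g, "sex": "F" if i % 2 == 0 else "M"})
    return np.stack(configs), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text writers / readers
# ---------------------------------------------------------------------------

def write_occurrences_csv(occ: pd.DataFrame, path: str) -> None:
    occ.to_csv(path, index=False)


def write_ascii_grid(layer: np.ndarray, path: str, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid writer (single band, plain text)."""
    nr, nc = layer.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {nodata}\n"
    )
    body = np.where(np.isfinite(layer), layer, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str) -> np.ndarray:
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = grid.reshape(int(meta["nrows"]), int(meta["ncols"]))
    grid[grid == meta["nodata_value"]] = np.nan
    return grid


def write_env_stack(env: EnvStack, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    for name, layer in env.layers.items():
        write_ascii_grid(layer, os.path.join(outdir, f"{name}.asc"))


def read_env_stack(outdir: str) -> EnvStack:
    layers = {}
    for fn in sorted(os.listdir(outdir)):
        if fn.endswith(".asc"):
            layers[fn[:-4]] = read_ascii_grid(os.path.join(outdir, fn))
    if not layers:
        raise FileNotFoundError(f"no .asc layers in {outdir}")
    return EnvStack(layers)


_GT_CODE = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Minimal biallelic GT-only VCF; CHROM is the parent RAD locus."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in pd.unique(G.locus_ids):
            fh.write(f"##contig=<ID=locus{locus},length=110>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids)
            + "\n"
        )
        for j in range(G.n_snps):
            gts = "\t".join(_GT_CODE[int(g)] for g in G.calls[:, j])
            fh.write(
                f"locus{G.locus_ids[j]}\t{int(G.positions[j]) + 1}\t{G.snp_ids[j]}"
                f"\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str, populations: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF back into a :class:`GenotypeMatrix`.

    Uses cyvcf2 when importable, falling back to a line parser for the
    minimal dialect written by :func:`write_vcf`.
    """
    try:
        from cyvcf2 import VCF  # type: ignore

        v = VCF(path)
        samples = list(v.samples)
        calls, loci, pos, ids = [], [], [], []
        for rec in v:
            gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            row = np.where(gt == 3, 2, np.where(gt == 2, -1, gt))
            calls.append(row.astype(np.int8))
            loci.append(rec.CHROM.removeprefix("locus"))
            pos.append(rec.POS - 1)
            ids.append(rec.ID or f"snp{len(ids)}")
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        inv = {v: k for k, v in _GT_CODE.items()}
        samples, calls, loci, pos, ids = [], [], [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    samples = line.rstrip("\n").split("\t")[9:]
                    continue
                f = line.rstrip("\n").split("\t")
                calls.append(np.array([inv[g] for g in f[9:]], dtype=np.int8))
                loci.append(f[0].removeprefix("locus"))
                pos.append(int(f[1]) - 1)
                ids.append(f[2])
    calls_arr = np.stack(calls, axis=1) if calls else np.zeros((len(samples), 0), np.int8)
    try:
        locus_ids = np.array([int(x) for x in loci])
    except ValueError:
        locus_ids = np.array(loci)
    pops = np.array([populations.get(s, "pop0") if populations else "pop0" for s in samples])
    return GenotypeMatrix(
        calls=calls_arr,
        individual_ids=samples,
        populations=pops,
        locus_ids=locus_ids,
        positions=np.array(pos),
        snp_ids=ids,
    )


def write_012_tsv(G: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(G.calls, index=G.individual_ids, columns=G.snp_ids)
    df.replace(-1, pd.NA).to_csv(path, sep="\t")


def read_012_tsv(path: str, populations: Mapping[str, str] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    calls = df.fillna(-1).to_numpy().astype(np.int8)
    pops = np.array(
        [populations.get(s, "pop0") if populations else "pop0" for s in df.index]
    )
    return GenotypeMatrix(
        calls=calls,
        individual_ids=list(df.index.astype(str)),
        populations=pops,
        locus_ids=np.arange(calls.shape[1]),
        positions=np.zeros(calls.shape[1], dtype=int),
        snp_ids=list(df.columns.astype(str)),
    )


def write_popmap(G: GenotypeMatrix, path: str) -> None:
    pd.DataFrame({"individual": G.individual_ids, "population": G.populations}).to_csv(
        path, sep="\t", index=False
    )


def write_qmatrix(G: GenotypeMatrix, path: str) -> None:
    if G.Q is None:
        raise ValueError("genotype matrix carries no Q matrix")
    k = G.Q.shape[1]
    pd.DataFrame(
        G.Q, index=G.individual_ids, columns=[f"Q{i + 1}" for i in range(k)]
    ).to_csv(path, sep="\t")


def read_qmatrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
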