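"""Synthetic inputs with known ground truth.

Emulates the data structures of a two-batch, two-genotype bulk RNA-seq
experiment (negative-binomial counts with batch intercept shifts and
log-normal library-size factors, a sparse set of true knockout
effects), 3'UTRs with implanted canonical miRNA seed sites, and the
long-format Ct and MFI tables the quantification procedures consume.
Every simulator is a pure function of its configuration and seed and
returns the ground truth alongside the data, so parameter-recovery
and calibration tests have an exact reference.

Negative-binomial parameterization throughout the package:
``var = mu + alpha * mu**2`` with per-gene dispersion ``alpha``
(equivalently NB size ``r = 1/alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ilc2kit.counts import CountMatrix

_SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_RNA = "ACGU"
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass
class SimCountConfig:
    """Configuration of the count simulator.

    Defaults emulate a small bulk RNA-seq study: 2 batches x 2
    genotypes with 4 samples per cell, ~10% of genes carrying a true
    knockout effect of |log fold change| = log 2, moderate
    overdispersion (alpha = 0.1) and mild batch/library-size shifts.
    Base means are drawn log-uniform over (100, 10000), which at the
    default 500 genes yields ~1e6 counted reads per sample — a typical
    bulk library depth scaled to the simulated gene count.
    """

    n_genes: int = 500
    n_per_cell: int = 4
    n_batches: int = 2
    prop_de: float = 0.1
    lfc_magnitude: float = float(np.log(2.0))
    base_mean_log_range: tuple[float, float] = (np.log(100.0), np.log(10000.0))
    dispersion: float = 0.1
    batch_intercept_shift: float = 0.3
    libsize_log_sd: float = 0.2
    dispersion_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_per_cell < 1 or self.n_batches < 1:
            raise ValueError("n_genes, n_per_cell and n_batches must be >= 1")
        if not 0.0 <= self.prop_de <= 1.0:
            raise ValueError("prop_de must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.libsize_log_sd < 0 or self.dispersion_log_sd < 0:
            raise ValueError("log-sd parameters must be >= 0")
        lo, hi = self.base_mean_log_range
        if not lo <= hi:
            raise ValueError("base_mean_log_range must be (low, high)")


@dataclass
class SimTruth:
    """Ground truth emitted by a simulator."""

    de_genes: set = field(default_factory=set)
    true_lfc: pd.Series | None = None
    true_size_factors: pd.Series | None = None
    true_dispersion: pd.Series | None = None
    extra: dict = field(default_factory=dict)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB(mu, alpha) via the Gamma-Poisson mixture."""
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def simulate_counts(config: SimCountConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate a two-genotype, multi-batch NB count matrix.

    Counts for gene g in sample j are drawn
    ``NB(mean = s_j * exp(intercept_g + shift_{b(j)} + x_j * lfc_g),
    dispersion alpha_g)`` with ``x_j = 1`` for KO samples.  Batch
    shifts alternate sign around zero with magnitude
    ``batch_intercept_shift``; per-sample size factors are log-normal
    with sd ``libsize_log_sd`` and renormalized to geometric mean 1
    within each batch; gene dispersions are log-normal around the
    configured alpha.  Exactly ``round(prop_de * n_genes)`` genes get
    a nonzero effect, half up / half down (extra gene goes up).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, B, npc = config.n_genes, config.n_batches, config.n_per_cell
    n_samples = 2 * B * npc

    gene_ids = [f"gene{g:04d}" for g in range(G)]
    sample_ids, genotypes, batches = [], [], []
    for b in range(1, B + 1):
        for geno in ("WT", "KO"):
            for r in range(1, npc + 1):
                sample_ids.append(f"b{b}_{geno}_{r}")
                genotypes.append(geno)
                batches.append(b)
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "genotype": genotypes, "batch": batches}
    )

    lo, hi = config.base_mean_log_range
    intercepts = rng.uniform(lo, hi, size=G)
    alpha = config.dispersion * np.exp(
        rng.normal(0.0, config.dispersion_log_sd, size=G)
        - 0.5 * config.dispersion_log_sd**2
    )

    n_de = round(config.prop_de * G)
    de_idx = rng.choice(G, size=n_de, replace=False)
    lfc = np.zeros(G)
    signs = np.where(np.arange(n_de) < (n_de + 1) // 2, 1.0, -1.0)
    lfc[de_idx] = signs * config.lfc_magnitude

    # batch shifts symmetric around 0 so the grand intercept is stable
    if B == 1:
        shifts = np.zeros(1)
    else:
        shifts = config.batch_intercept_shift * np.linspace(-1.0, 1.0, B)

    sf = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))
    batch_arr = np.asarray(batches)
    for b in range(1, B + 1):
        idx = batch_arr == b
        sf[idx] /= np.exp(np.mean(np.log(sf[idx])))

    is_ko = (meta["genotype"] == "KO").to_numpy().astype(float)
    log_mu = (
        intercepts[:, None]
        + shifts[batch_arr - 1][None, :]
        + lfc[:, None] * is_ko[None, :]
        + np.log(sf)[None, :]
    )
    counts = _nb_sample(rng, np.exp(log_mu), alpha[:, None])

    cm = CountMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_meta=meta,
    )
    truth = SimTruth(
        de_genes={gene_ids[i] for i in de_idx},
        true_lfc=pd.Series(lfc, index=gene_ids),
        true_size_factors=pd.Series(sf, index=sample_ids),
        true_dispersion=pd.Series(alpha, index=gene_ids),
        extra={
            "intercepts": pd.Series(intercepts, index=gene_ids),
            "batch_shifts": pd.Series(shifts, index=range(1, B + 1)),
        },
    )
    return cm, truth


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _site_sequence(mir: str, site_type: str) -> str:
    """UTR-strand (5'->3') sequence of a canonical site for ``mir``."""
    core = _revcomp(mir[1:7])  # complements miR positions 2-7
    m8 = _COMPLEMENT[mir[7]]   # complements miR position 8, 5' of core on UTR
    if site_type == "6mer":
        return core
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "8mer":
        return m8 + core + "A"
    raise ValueError(f"unknown site type {site_type!r}; expected one of {_SEED_CLASSES}")


def simulate_utr(
    mir_seq: str,
    n_sites: int,
    site_type: str = "8mer",
    utr_length: int = 200,
    seed: int = 0,
) -> tuple[str, list[tuple[int, int]]]:
    """Generate a synthetic 3'UTR with ``n_sites`` implanted canonical
    sites for ``mir_seq`` and no accidental seed match elsewhere.

    Background is uniform over A/C/G/U, rejection-sampled so the only
    occurrences of the 6mer seed core are the implants.  Returns the
    UTR (5'->3') and the implanted intervals, 0-based half-open.
    """
    mir = str(mir_seq).upper().replace("T", "U")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if any(c not in _RNA for c in mir):
        raise ValueError("miRNA sequence contains non-ACGU characters")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    site = _site_sequence(mir, site_type)
    L = len(site)
    if utr_length < n_sites * (L + 2):
        raise ValueError(
            f"utr_length {utr_length} too short to pack {n_sites} "
            f"{site_type} sites with spacing"
        )
    rng = np.random.default_rng(seed)
    core = _revcomp(mir[1:7])

    # choose non-overlapping, non-adjacent start positions (1 nt gap so
    # implant junctions cannot merge into new cores)
    if n_sites == 0:
        starts: list[int] = []
    else:
        free = utr_length - n_sites * (L + 1)
        cuts = np.sort(rng.integers(0, free + 1, size=n_sites))
        starts = [int(cuts[k] + k * (L + 1)) for k in range(n_sites)]

    has_m8 = site_type in ("7mer-m8", "8mer")
    has_a1 = site_type in ("7mer-A1", "8mer")
    m8_comp = _COMPLEMENT[mir[7]]

    # flank positions whose base must not upgrade the implanted class:
    # 5' of the core must not complement miR position 8, 3' must not be A
    disallowed: dict[int, set[str]] = {}
    for s in starts:
        c = s + (1 if has_m8 else 0)
        if not has_m8 and c - 1 >= 0:
            disallowed.setdefault(c - 1, set()).add(m8_comp)
        if not has_a1 and c + 6 < utr_length:
            disallowed.setdefault(c + 6, set()).add("A")

    for _attempt in range(2000):
        bases = list(rng.choice(list(_RNA), size=utr_length))
        for pos, bad in disallowed.items():
            allowed = [b for b in _RNA if b not in bad]
            bases[pos] = allowed[int(rng.integers(len(allowed)))]
        for s in starts:
            bases[s : s + L] = site
        for pos, bad in disallowed.items():  # implants may have overwritten
            if bases[pos] in bad:
                allowed = [b for b in _RNA if b not in bad]
                bases[pos] = allowed[int(rng.integers(len(allowed)))]
        candidate = "".join(bases)
        # reject accidental cores outside the implanted intervals
        implant_core_starts = {s + (1 if has_m8 else 0) for s in starts}
        ok = True
        pos = candidate.find(core)
        while pos != -1:
            if pos not in implant_core_starts:
                ok = False
                break
            pos = candidate.find(core, pos + 1)
        if ok:
            return candidate, [(s, s + L) for s in starts]
        # resample background only; implant positions stay fixed
    raise RuntimeError("could not sample a clean background UTR")


def simulate_ct(
    true_fold_changes: dict[str, float],
    ct_noise_sd: float = 0.2,
    n_reps: int = 3,
    seed: int = 0,
    reference_gene: str = "Gapdh",
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a long-format Ct table whose expected 2^-ddCt recovers
    the requested fold changes (treated vs control).

    For each target gene, treated-condition target Cts are shifted by
    ``-log2(fold)`` relative to control so that expected ddCt equals
    ``-log2(fold)``; Gaussian noise of sd ``ct_noise_sd`` cycles is
    added to every well.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    for g, f in true_fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for {g!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in true_fold_changes.items():
        shift = -np.log2(fold)
        for cond in ("control", "treated"):
            for r in range(1, n_reps + 1):
                sample = f"{cond}_{r}"
                ct_t = base_ct_target + (shift if cond == "treated" else 0.0)
                rows.append(
                    {
                        "sample": sample,
                        "condition": cond,
                        "role": "target",
                        "gene": gene,
                        "ct": ct_t + rng.normal(0.0, ct_noise_sd),
                    }
                )
                rows.append(
                    {
                        "sample": sample,
                        "condition": cond,
                        "role": "reference",
                        "gene": reference_gene,
                        "ct": base_ct_reference + rng.normal(0.0, ct_noise_sd),
                    }
                )
    table = pd.DataFrame(rows)
    truth = SimTruth(extra={"true_fold_changes": dict(true_fold_changes)})
    return table, truth


def simulate_reporter_mfi(
    knockdown: float = 0.5,
    n_reps: int = 4,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """MFI table for a two-channel reporter assay (NGFR readout,
    Thy1.1 transfection control), quadruplicate wells for an empty
    vector and a miRNA vector whose true normalized reporter value is
    ``knockdown``."""
    if not 0 < knockdown:
        raise ValueError("knockdown must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for vector, level in (("empty", 1.0), ("mir", knockdown)):
        for r in range(1, n_reps + 1):
            thy = 3000.0 * np.exp(rng.normal(0, noise_cv))
            ngfr = 1500.0 * level * np.exp(rng.normal(0, noise_cv))
            well = f"{vector}_{r}"
            rows.append({"well": well, "vector": vector, "marker": "NGFR", "mfi": ngfr})
            rows.append({"well": well, "vector": vector, "marker": "Thy1.1", "mfi": thy})
    return pd.DataFrame(rows), SimTruth(extra={"true_knockdown": knockdown})


def simulate_chimera_mfi(
    true_ratios: dict[str, float],
    n_hosts: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
    test_population: str = "CD45.2",
    reference_population: str = "CD45.1",
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-host MFI table for a mixed bone-marrow chimera: each host
    carries a test and a congenic reference population; marker MFIs on
    the test population are ``true_ratios[marker]`` times the
    reference, within-host."""
    rng = np.random.default_rng(seed)
    rows = []
    for h in range(1, n_hosts + 1):
        host = f"host{h}"
        for marker, ratio in true_ratios.items():
            if ratio <= 0:
                raise ValueError(f"ratio for {marker!r} must be > 0")
            ref = 1000.0 * np.exp(rng.normal(0, noise_cv))
            rows.append(
                {"host": host, "population": reference_population,
                 "marker": marker, "mfi": ref}
            )
            rows.append(
                {"host": host, "population": test_population,
                 "marker": marker, "mfi": ref * ratio}
            )
    return pd.DataFrame(rows), SimTruth(extra={"true_ratios": dict(true_ratios)})
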