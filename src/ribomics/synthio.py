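"""Synthetic matched multi-omics data with planted ground truth.

Three generators, all deterministic given their seed:

* :func:`generate_multiomics` — negative-binomial RNA-seq and Ribo-seq count
  matrices plus a log-normal TMT-like protein intensity matrix for a
  two-condition design, with per-gene effects planted on the mRNA, TE and
  protein channels according to configurable regulatory-class proportions.
* :func:`generate_footprints` — transcript-coordinate ribosome footprints
  whose A-site lands on CDS codons with probability proportional to
  per-codon pause multipliers, with a configurable read-length distribution.
* :func:`generate_annotation` — localisation and druggability tables plus a
  gene-set collection containing a positive-control set enriched for planted
  up-regulated genes.

Counts follow NB(mean mu, variance mu + alpha * mu^2); size factors are drawn
log-uniformly per sample and assay so that downstream normalization is
exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .normde import AbundanceMatrix
from .ribo import DEFAULT_PSITE_OFFSETS, SENSE_CODONS, STOP_CODONS, TranscriptModel

__all__ = [
    "SimulationConfig",
    "FootprintSimConfig",
    "MultiOmicsData",
    "generate_multiomics",
    "generate_footprints",
    "generate_annotation",
    "generate_transcript",
    "dteg_class_from_effects",
    "group_from_effects",
    "DTEG_CLASSES",
    "GENE_CLASSES",
]

DTEG_CLASSES = ("forwarded", "exclusive", "intensified", "buffered")
GENE_CLASSES = DTEG_CLASSES + ("concordant_protein", "discordant_protein", "null")

LOCALISATIONS = ("IC", "SP", "TM", "SPTM")

_DEFAULT_PROPORTIONS = {
    "forwarded": 0.06,
    "exclusive": 0.06,
    "intensified": 0.04,
    "buffered": 0.04,
    "concordant_protein": 0.05,
    "discordant_protein": 0.03,
    "null": 0.72,
}

_DEFAULT_LENGTH_DIST = {28: 0.15, 29: 0.25, 30: 0.30, 31: 0.20, 32: 0.10}


@dataclass
class SimulationConfig:
    """Parameters of the matched multi-omics simulation."""

    n_genes: int = 2000
    n_reps_per_condition: int = 4
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    class_proportions: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    effect_log2fc: float = 1.0
    protein_sd_log2: float = 0.25
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_reps_per_condition < 2:
            raise ValueError("n_reps_per_condition must be at least 2")
        for name in ("baseline_mean", "nb_dispersion", "effect_log2fc", "protein_sd_log2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("size_factor_range must be a pair of positive reals, low <= high")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be nonnegative")


class MultiOmicsData(NamedTuple):
    rna: AbundanceMatrix
    rpf: AbundanceMatrix
    protein: AbundanceMatrix
    truth: pd.DataFrame


def dteg_class_from_effects(beta_rna: float, beta_te: float) -> str:
    """Regulatory class implied by planted mRNA/TE effects."""
    if beta_te != 0 and beta_rna == 0:
        return "exclusive"
    if beta_te != 0 and beta_rna != 0:
        return "intensified" if np.sign(beta_te) == np.sign(beta_rna) else "buffered"
    if beta_rna != 0:
        return "forwarded"
    return "none"


def group_from_effects(beta_rna: float, beta_protein: float) -> int:
    """Concordance group (1-5) implied by planted mRNA/protein effects.

    A layer with zero planted effect carries no direction; when the other
    layer has one, the gene is grouped concordantly with it.
    """
    if beta_rna == 0 and beta_protein == 0:
        return 1
    r = np.sign(beta_rna) or np.sign(beta_protein)
    p = np.sign(beta_protein) or np.sign(beta_rna)
    if r > 0:
        return 2 if p > 0 else 3
    return 4 if p > 0 else 5


def _class_counts(proportions: dict[str, float], n_genes: int) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    quotas = {c: proportions.get(c, 0.0) * n_genes for c in GENE_CLASSES}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = n_genes - sum(counts.values())
    by_remainder = sorted(GENE_CLASSES, key=lambda c: (counts[c] - quotas[c], c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    k = 1.0 / dispersion
    return rng.negative_binomial(k, k / (k + mean))


def generate_multiomics(config: SimulationConfig) -> MultiOmicsData:
    """Simulate matched RNA-seq, Ribo-seq and protein matrices with truth.

    RNA counts are NB with mean ``s_j * q_i * 2^(x_j * beta_rna_i)``; RPF
    counts use ``beta_rna_i + beta_te_i`` in the exponent; protein
    intensities are log2-normal around a baseline shifted by
    ``x_j * beta_protein_i``, where ``x_j`` indicates the treated condition.
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_reps_per_condition
    e = config.effect_log2fc

    counts = _class_counts(config.class_proportions, G)
    labels = np.concatenate([np.repeat(c, k) for c, k in counts.items()])
    labels = labels[rng.permutation(G)]
    signs = rng.choice([-1.0, 1.0], size=G)

    beta_rna = np.zeros(G)
    beta_te = np.zeros(G)
    beta_prot = np.zeros(G)
    beta_rna[np.isin(labels, ("forwarded", "intensified", "buffered", "concordant_protein", "discordant_protein"))] = 1
    beta_rna *= signs * e
    beta_te[labels == "exclusive"] = signs[labels == "exclusive"] * e
    beta_te[labels == "intensified"] = signs[labels == "intensified"] * e
    beta_te[labels == "buffered"] = -signs[labels == "buffered"] * e
    beta_prot[labels == "concordant_protein"] = signs[labels == "concordant_protein"] * e
    beta_prot[labels == "discordant_protein"] = -signs[labels == "discordant_protein"] * e

    gene_ids = [f"G{i:05d}" for i in range(G)]
    samples = [f"ctrl_{j + 1}" for j in range(n)] + [f"trt_{j + 1}" for j in range(n)]
    conditions = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}
    x = np.r_[np.zeros(n), np.ones(n)]

    q = config.baseline_mean * 2.0 ** rng.normal(0.0, config.baseline_log2_sd, size=G)
    lo, hi = config.size_factor_range
    sf = {
        assay: np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n))
        for assay in ("rna", "rpf", "protein")
    }

    mu_rna = sf["rna"][None, :] * q[:, None] * 2.0 ** (x[None, :] * beta_rna[:, None])
    mu_rpf = sf["rpf"][None, :] * q[:, None] * 2.0 ** (x[None, :] * (beta_rna + beta_te)[:, None])
    rna = _nb_draw(rng, mu_rna, config.nb_dispersion)
    rpf = _nb_draw(rng, mu_rpf, config.nb_dispersion)

    # Intensity scale is arbitrary for TMT-like reporters; keep it well above
    # the count scale so completeness filtering, not discreteness, matters.
    base_prot = q * 50.0
    log2_int = (
        np.log2(sf["protein"])[None, :]
        + np.log2(base_prot)[:, None]
        + x[None, :] * beta_prot[:, None]
        + rng.normal(0.0, config.protein_sd_log2, size=(G, 2 * n))
    )
    protein = 2.0**log2_int

    truth = pd.DataFrame(
        {
            "true_class": labels,
            "true_log2fc_rna": beta_rna,
            "true_log2fc_te": beta_te,
            "true_log2fc_protein": beta_prot,
            "true_dteg_class": [dteg_class_from_effects(r, t) for r, t in zip(beta_rna, beta_te)],
            "true_group": [group_from_effects(r, p) for r, p in zip(beta_rna, beta_prot)],
            "localisation": rng.choice(LOCALISATIONS, size=G, p=[0.60, 0.15, 0.15, 0.10]),
            "druggable": rng.random(G) < 0.3,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    has_ligand = truth["druggable"] & (rng.random(G) < 0.5)
    truth["has_ligand"] = has_ligand
    truth["has_approved_drug"] = has_ligand & (rng.random(G) < 0.4)

    def _mat(values: np.ndarray) -> AbundanceMatrix:
        df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
        return AbundanceMatrix(df, dict(conditions))

    return MultiOmicsData(_mat(rna.astype(float)), _mat(rpf.astype(float)), _mat(protein), truth)


@dataclass
class FootprintSimConfig:
    """Parameters of the footprint simulation."""

    n_reads: int = 100_000
    length_distribution: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_LENGTH_DIST))
    pause_multipliers: dict[str, float] = field(default_factory=dict)
    offsets: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_PSITE_OFFSETS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be nonnegative")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length distribution sums to {total}, expected 1")
        if any(v <= 0 for v in self.pause_multipliers.values()):
            raise ValueError("pause multipliers must be strictly positive")
        missing = set(self.length_distribution) - set(self.offsets)
        if missing:
            raise ValueError(f"no P-site offset for simulated lengths {sorted(missing)}")


def generate_transcript(
    transcript_id: str,
    n_codons: int,
    utr5_len: int = 30,
    utr3_len: int = 30,
    seed: int = 0,
    codon_pool: tuple[str, ...] = SENSE_CODONS,
) -> TranscriptModel:
    """Random coding transcript: ATG, random sense codons, one stop codon."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons (start, one sense, stop)")
    rng = np.random.default_rng(seed)
    body = rng.choice(codon_pool, size=n_codons - 2)
    cds = "ATG" + "".join(body) + str(rng.choice(STOP_CODONS))
    utr5 = "".join(rng.choice(list("ACGT"), size=utr5_len))
    utr3 = "".join(rng.choice(list("ACGT"), size=utr3_len))
    return TranscriptModel(transcript_id, utr5_len, 3 * n_codons, utr3_len, utr5 + cds + utr3)


def generate_footprints(model: TranscriptModel, config: FootprintSimConfig) -> pd.DataFrame:
    """Simulate footprints whose A-site samples CDS codons by pause weight.

    Returns a table with columns ``transcript_id``, ``pos5`` (0-based 5' end)
    and ``length``.  Reads whose implied 5' end would fall outside the
    transcript are resampled into bounds via rejection of the read length,
    never of the codon, so codon proportions are preserved.
    """
    if not model.coding or model.sequence is None:
        raise ValueError("footprint simulation needs a coding transcript with sequence")
    if model.n_codons < 3:
        raise ValueError("CDS shorter than 3 codons")
    rng = np.random.default_rng(config.seed)
    if config.n_reads == 0:
        return pd.DataFrame(columns=["transcript_id", "pos5", "length"])

    codons = model.cds_codons()
    weights = np.array([config.pause_multipliers.get(c, 1.0) for c in codons])
    prob = weights / weights.sum()
    codon_idx = rng.choice(len(codons), size=config.n_reads, p=prob)

    lengths_avail = np.array(sorted(config.length_distribution))
    length_p = np.array([config.length_distribution[k] for k in lengths_avail])
    lengths = rng.choice(lengths_avail, size=config.n_reads, p=length_p)

    offsets = np.array([config.offsets[int(k)] for k in lengths])
    psite = model.utr5_len + 3 * codon_idx - 3
    pos5 = psite - offsets
    ok = (pos5 >= 0) & (pos5 + lengths <= model.length)
    if not ok.all():
        # keep the sampled codon; fall back to the shortest feasible length
        short = lengths_avail.min()
        pos5_fix = psite - config.offsets[int(short)]
        fixable = ~ok & (pos5_fix >= 0) & (pos5_fix + short <= model.length)
        pos5 = np.where(fixable, pos5_fix, pos5)
        lengths = np.where(fixable, short, lengths)
        ok = (pos5 >= 0) & (pos5 + lengths <= model.length)
    return pd.DataFrame(
        {
            "transcript_id": model.transcript_id,
            "pos5": pos5[ok].astype(int),
            "length": lengths[ok].astype(int),
        }
    )


def generate_annotation(
    truth: pd.DataFrame,
    n_gene_sets: int = 20,
    set_size_range: tuple[int, int] = (15, 60),
    seed: int = 0,
    control_set_size: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], dict[str, str]]:
    """Localisation table, druggability table and a GMT-ready collection.

    The collection contains ``POSITIVE_CONTROL``, a set drawn from planted
    mRNA-up genes (for GSEA positive control), and ``n_gene_sets`` random
    sets.  The returned metadata names the control set and is meant for the
    truth sidecar.
    """
    lo, hi = set_size_range
    n_genes = len(truth)
    if lo < 2 or hi > n_genes or hi < lo:
        raise ValueError(f"set_size_range must lie within [2, {n_genes}]")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.index)

    loc_table = truth[["localisation"]].copy()
    drug_table = truth[["druggable", "has_ligand", "has_approved_drug"]].copy()

    up = genes[truth["true_log2fc_rna"].to_numpy() > 0]
    k = min(control_set_size, len(up))
    if k < 2:
        raise ValueError("not enough planted up-regulated genes for a control set")
    sets: dict[str, list[str]] = {
        "POSITIVE_CONTROL": sorted(rng.choice(up, size=k, replace=False))
    }
    for i in range(n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_{i:03d}"] = sorted(rng.choice(genes, size=size, replace=False))
    meta = {"enriched_set": "POSITIVE_CONTROL"}
    return loc_table, drug_table, sets, meta
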