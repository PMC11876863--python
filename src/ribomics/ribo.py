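"""Ribosome-profiling analytics.

Covers P/A-site assignment from footprint 5' ends, library QC (length
histogram, region fractions), translation-efficiency estimation and testing,
regulatory classification of differential-TE genes, codon occupancy at the
A/P sites, and per-codon pause scores.

Coordinates are 0-based, half-open, in transcript space.  The codon index of
a site at transcript position ``s`` on a coding transcript is
``(s - utr5_len) // 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .normde import NormalizedMatrix, bh_adjust, welch_t
from .report import percent

__all__ = [
    "TranscriptModel",
    "DEFAULT_PSITE_OFFSETS",
    "assign_psites",
    "riboseq_qc",
    "RiboQCReport",
    "compute_te",
    "differential_te",
    "TEResult",
    "classify_dteg",
    "dteg_partition",
    "flagged_percent",
    "codon_occupancy",
    "pause_scores",
    "ALL_CODONS",
    "STOP_CODONS",
]

#: Read-length-dependent offset from the footprint 5' end to the P-site.
#: Standard mammalian monosome convention; configurable everywhere it is used.
DEFAULT_PSITE_OFFSETS: dict[int, int] = {28: 12, 29: 12, 30: 12, 31: 12, 32: 13, 33: 13, 34: 13}

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

FOOTPRINT_COLUMNS = ("transcript_id", "pos5", "length")


@dataclass
class TranscriptModel:
    """CDS/UTR geometry of a transcript, optionally with its sequence."""

    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str | None = None
    coding: bool = True

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError("region lengths must be nonnegative")
        if self.coding and self.cds_len % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {self.cds_len} not divisible by 3")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.transcript_id}: sequence length != utr5+cds+utr3")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    def cds_codons(self) -> list[str]:
        if self.sequence is None:
            raise ValueError(f"{self.transcript_id}: sequence required for codon analyses")
        cds = self.sequence[self.utr5_len : self.utr5_len + self.cds_len]
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def assign_psites(
    footprints: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    offsets: Mapping[int, int] | None = None,
    default_offset: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Annotate footprints with P-site and A-site transcript positions.

    ``psite = pos5 + offset(length)``; ``asite = psite + 3``.  Records whose
    P-site falls outside the transcript are dropped and counted.

    Returns the annotated table and the number of dropped records.

    Raises
    ------
    KeyError
        If a read length has no offset and no ``default_offset`` is given.
    """
    offsets = dict(DEFAULT_PSITE_OFFSETS if offsets is None else offsets)
    fp = footprints.copy()
    lengths = fp["length"].to_numpy()
    unknown = sorted(set(int(x) for x in lengths) - set(offsets))
    if unknown:
        if default_offset is None:
            raise KeyError(f"no P-site offset for read lengths {unknown} and no default")
        for ln in unknown:
            offsets[ln] = default_offset
    off = np.array([offsets[int(x)] for x in lengths], dtype=int)
    fp["psite"] = fp["pos5"].to_numpy() + off
    fp["asite"] = fp["psite"] + 3
    tlen = fp["transcript_id"].map(lambda t: models[t].length).to_numpy()
    ok = (fp["psite"].to_numpy() >= 0) & (fp["psite"].to_numpy() < tlen)
    return fp.loc[ok].reset_index(drop=True), int((~ok).sum())


@dataclass
class RiboQCReport:
    length_histogram: dict[int, int]
    region_fractions: dict[str, float]
    n_reads: int = 0


def riboseq_qc(footprints: pd.DataFrame, models: Mapping[str, TranscriptModel]) -> RiboQCReport:
    """Length histogram and 5'UTR/ORF/3'UTR/other fractions by P-site."""
    if len(footprints) == 0:
        raise ValueError("empty footprint table")
    if "psite" not in footprints.columns:
        raise ValueError("P-sites not assigned; run assign_psites first")
    hist = {int(k): int(v) for k, v in footprints["length"].value_counts().sort_index().items()}
    counts = {"utr5": 0, "orf": 0, "utr3": 0, "other": 0}
    for tid, sub in footprints.groupby("transcript_id"):
        model = models[tid]
        psites = sub["psite"].to_numpy()
        if not model.coding:
            counts["other"] += len(psites)
            continue
        cds_start = model.utr5_len
        cds_end = model.utr5_len + model.cds_len
        counts["utr5"] += int((psites < cds_start).sum())
        counts["orf"] += int(((psites >= cds_start) & (psites < cds_end)).sum())
        counts["utr3"] += int((psites >= cds_end).sum())
    total = len(footprints)
    fractions = {k: v / total for k, v in counts.items()}
    return RiboQCReport(hist, fractions, total)


@dataclass
class TEResult:
    """Per-sample log2 TE plus (after :func:`differential_te`) test results.

    ``log2_te`` is gene-by-sample; ``stats`` holds per-gene ``delta_log2_te``,
    ``p``, ``q``, ``te_significant`` and ``direction`` once the differential
    step has run.  ``excluded`` records genes that failed the expression
    filter, with the reason.
    """

    log2_te: pd.DataFrame
    conditions: Mapping[str, str]
    excluded: pd.DataFrame
    stats: pd.DataFrame | None = None


def compute_te(
    rna: NormalizedMatrix,
    rpf: NormalizedMatrix,
    min_mean: float = 1.0,
    pseudocount: float = 0.5,
) -> TEResult:
    """Per-sample log2 translation efficiency (RPF over mRNA).

    ``log2_te_ij = log2(rpf_ij + pc) - log2(rna_ij + pc)`` for genes whose
    mean normalized abundance is at least ``min_mean`` in both assays.  Both
    matrices must already be size-factor normalized and share sample ids and
    condition labels.
    """
    genes = rna.data.index.intersection(rpf.data.index)
    if len(genes) == 0:
        raise ValueError("no overlapping genes between RNA and RPF matrices")
    if list(rna.data.columns) != list(rpf.data.columns):
        raise ValueError("RNA and RPF matrices must share sample ids in order")
    rna_sub = rna.data.loc[genes]
    rpf_sub = rpf.data.loc[genes]
    rna_ok = rna_sub.mean(axis=1) >= min_mean
    rpf_ok = rpf_sub.mean(axis=1) >= min_mean
    keep = rna_ok & rpf_ok
    reasons = np.where(
        ~rna_ok & ~rpf_ok, "low_rna_and_rpf", np.where(~rna_ok, "low_rna", "low_rpf")
    )
    excluded = pd.DataFrame({"reason": reasons[~keep]}, index=genes[~keep])
    log2_te = np.log2(rpf_sub.loc[keep] + pseudocount) - np.log2(rna_sub.loc[keep] + pseudocount)
    return TEResult(log2_te, dict(rna.conditions), excluded)


def differential_te(
    te: TEResult,
    threshold: float = 0.05,
    treated: str = "treated",
    control: str = "control",
) -> TEResult:
    """Welch test on replicate log2 TE between conditions; BH across genes."""
    groups: dict[str, list[str]] = {}
    for s in te.log2_te.columns:
        groups.setdefault(te.conditions[s], []).append(s)
    for label in (treated, control):
        if label not in groups or len(groups[label]) < 2:
            raise ValueError(f"condition {label!r} needs at least 2 replicates")
    a = te.log2_te[groups[treated]].to_numpy()
    b = te.log2_te[groups[control]].to_numpy()
    t, df, p, degenerate = welch_t(a, b)
    delta = a.mean(axis=1) - b.mean(axis=1)
    q = bh_adjust(p)
    direction = np.full(delta.shape, "flat", dtype=object)
    direction[delta > 0] = "up"
    direction[delta < 0] = "down"
    te.stats = pd.DataFrame(
        {
            "delta_log2_te": delta,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "te_significant": q < threshold,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=te.log2_te.index,
    )
    te.stats.index.name = "gene_id"
    return te


def classify_dteg(rna_de: pd.DataFrame, te_stats: pd.DataFrame) -> pd.DataFrame:
    """Regulatory classification from mRNA-level and TE-level tests.

    Rule table over the shared gene universe::

        exclusive    te_sig and not rna_sig
        intensified  te_sig and rna_sig, same direction
        buffered     te_sig and rna_sig, opposite direction
        forwarded    rna_sig and not te_sig
        none         neither significant

    A significant layer with direction ``flat`` (log2FC exactly 0) cannot be
    oriented; such genes are flagged ``unclassifiable`` instead of being
    silently binned.
    """
    genes = rna_de.index.intersection(te_stats.index)
    rna_sig = rna_de.loc[genes, "significant"].to_numpy(dtype=bool)
    rna_dir = rna_de.loc[genes, "direction"].to_numpy(dtype=object)
    te_sig = te_stats.loc[genes, "te_significant"].to_numpy(dtype=bool)
    te_dir = te_stats.loc[genes, "direction"].to_numpy(dtype=object)

    unclassifiable = (rna_sig & (rna_dir == "flat")) | (te_sig & (te_dir == "flat"))
    cls = np.full(len(genes), "none", dtype=object)
    cls[rna_sig & ~te_sig] = "forwarded"
    cls[te_sig & ~rna_sig] = "exclusive"
    both = te_sig & rna_sig
    cls[both & (rna_dir == te_dir)] = "intensified"
    cls[both & (rna_dir != te_dir)] = "buffered"
    cls[unclassifiable] = "unclassifiable"

    out = pd.DataFrame(
        {
            "rna_sig": rna_sig,
            "rna_dir": rna_dir,
            "te_sig": te_sig,
            "te_dir": te_dir,
            "dteg_class": cls,
            "unclassifiable": unclassifiable,
        },
        index=genes,
    )
    out.index.name = "gene_id"
    return out


def dteg_partition(records: pd.DataFrame) -> dict[str, int]:
    """Class counts plus the implied DTEG total.

    The total counts every gene whose class entails a TE change
    (exclusive, intensified, buffered).
    """
    counts = records["dteg_class"].value_counts().to_dict()
    summary = {c: int(counts.get(c, 0)) for c in ("exclusive", "intensified", "buffered", "forwarded", "none")}
    summary["dteg_total"] = summary["exclusive"] + summary["intensified"] + summary["buffered"]
    return summary


def flagged_percent(table: pd.DataFrame, column: str, ndigits: int = 1) -> float:
    """Percentage of rows with a true flag in ``column`` (e.g. occupancy-up)."""
    if len(table) == 0:
        raise ValueError("empty table")
    return percent(int(table[column].sum()), len(table), ndigits)


def _codon_site_counts(
    footprints: pd.DataFrame,
    model: TranscriptModel,
    site_col: str,
    edge_trim: int,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-codon site counts and the mask of non-trimmed CDS codons."""
    n_codons = model.n_codons
    if n_codons <= 2 * edge_trim:
        return None
    pos = footprints.loc[footprints["transcript_id"] == model.transcript_id, site_col].to_numpy()
    in_cds = (pos >= model.utr5_len) & (pos < model.utr5_len + model.cds_len)
    codon_idx = (pos[in_cds] - model.utr5_len) // 3
    counts = np.bincount(codon_idx.astype(int), minlength=n_codons).astype(float)
    included = np.zeros(n_codons, dtype=bool)
    included[edge_trim : n_codons - edge_trim] = True
    return counts, included


def codon_occupancy(
    footprints: pd.DataFrame,
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    site: str = "A",
    edge_trim: int = 5,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Mean normalized footprint density per codon identity at the A or P site.

    For every coding transcript with mean site-count per non-trimmed CDS
    codon of at least ``min_coverage``, per-codon density is the site count
    divided by the transcript mean; occupancy per codon identity is the
    position-count-weighted mean density across transcripts.  The weighted
    mean over all identities is 1 by construction.
    """
    if site not in ("A", "P"):
        raise ValueError("site must be 'A' or 'P'")
    if len(footprints) == 0:
        raise ValueError("empty footprint table")
    site_col = "asite" if site == "A" else "psite"
    if site_col not in footprints.columns:
        raise ValueError("sites not assigned; run assign_psites first")
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}

    dens_sum = {c: 0.0 for c in ALL_CODONS}
    n_pos = {c: 0 for c in ALL_CODONS}
    n_passing = 0
    for model in models.values():
        if not model.coding or model.sequence is None:
            continue
        got = _codon_site_counts(footprints, model, site_col, edge_trim)
        if got is None:
            continue
        counts, included = got
        mean = counts[included].mean()
        if mean < min_coverage or mean == 0:
            continue
        n_passing += 1
        density = counts / mean
        codons = model.cds_codons()
        for i in np.flatnonzero(included):
            dens_sum[codons[i]] += density[i]
            n_pos[codons[i]] += 1
    if n_passing == 0:
        raise ValueError(f"no transcript passes min_coverage={min_coverage}")
    occupancy = [dens_sum[c] / n_pos[c] if n_pos[c] else np.nan for c in ALL_CODONS]
    out = pd.DataFrame(
        {"occupancy": occupancy, "n_positions": [n_pos[c] for c in ALL_CODONS], "site": site},
        index=pd.Index(ALL_CODONS, name="codon"),
    )
    return out


def pause_scores(
    footprints: pd.DataFrame,
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
    edge_trim: int = 5,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-codon pause scores: site count over the transcript mean count.

    Scores are emitted for non-trimmed CDS codons of every transcript with at
    least one footprint in that window; ``coverage_ok`` marks transcripts
    whose mean count meets ``min_coverage``.  By construction the mean score
    over a transcript's included codons is 1.
    """
    if len(footprints) == 0:
        raise ValueError("empty footprint table")
    if "psite" not in footprints.columns:
        raise ValueError("P-sites not assigned; run assign_psites first")
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    rows = []
    for model in models.values():
        if not model.coding:
            continue
        got = _codon_site_counts(footprints, model, "psite", edge_trim)
        if got is None:
            continue
        counts, included = got
        mean = counts[included].mean()
        if mean == 0:
            continue
        ok = mean >= min_coverage
        for i in np.flatnonzero(included):
            rows.append((model.transcript_id, int(i), counts[i] / mean, ok))
    return pd.DataFrame(rows, columns=["transcript_id", "codon_index", "pause_score", "coverage_ok"])
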