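"""Cross-omics integration.

Five-group mRNA/protein concordance stratification, localisation
subcategories, GO-term cross-checks, druggable-proteome overlap and
hierarchical clustering.

Group rule table (first element mRNA, second protein; SS = significant at
the chosen q threshold, NS = not; direction from the sign of log2FC)::

    Group 1  (NS, NS)
    Group 2  (SS-up,   SS-up)   (SS-up,   NS-up)   (NS-up,   SS-up)
    Group 3  (SS-up,   SS-down) (SS-up,   NS-down) (NS-up,   SS-down)
    Group 4  (SS-down, SS-down) (SS-down, NS-down) (NS-down, SS-down)
    Group 5  (SS-down, SS-up)   (NS-down, SS-up)   (SS-down, NS-up)

A non-significant layer with log2FC exactly 0 carries no direction and is
resolved concordantly with the other layer; a significant layer with zero
log2FC contradicts the table and is flagged unclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "stratify_five_groups",
    "assign_localisation",
    "subcategory_proportions",
    "go_crosscheck",
    "druggable_overlap",
    "DruggableSummary",
    "hierarchical_cluster",
    "ClusterResult",
    "LOCALISATION_CLASSES",
    "load_druggable_annotation",
]

LOCALISATION_CLASSES = ("SP", "TM", "IC", "SPTM")

CONCORDANT_GROUPS = (2, 4)
DISCORDANT_GROUPS = (3, 5)


def _classify_one(msig: bool, mdir: str, psig: bool, pdir: str) -> tuple[int, bool]:
    """Group and unclassifiable flag for one gene."""
    if (msig and mdir == "flat") or (psig and pdir == "flat"):
        return 0, True
    if not msig and not psig:
        return 1, False
    # resolve a direction-free NS layer concordantly with the other layer
    if mdir == "flat":
        mdir = pdir
    if pdir == "flat":
        pdir = mdir
    if mdir == "up":
        return (2, False) if pdir == "up" else (3, False)
    return (4, False) if pdir == "down" else (5, False)


def stratify_five_groups(
    rna: pd.DataFrame, protein: pd.DataFrame, threshold: float | None = None
) -> pd.DataFrame:
    """Assign every shared gene to one of the five concordance groups.

    Parameters
    ----------
    rna, protein
        Differential-result tables indexed by gene id with ``significant``,
        ``direction`` and ``log2fc`` columns (as produced by
        :func:`ribomics.normde.welch_differential`).
    threshold
        When given, significance is re-derived as ``q < threshold`` instead
        of trusting the stored flags.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene with ``group`` (1-5, or 0 when unclassifiable),
        ``mrna_sig``, ``prot_sig``, ``mrna_dir``, ``prot_dir`` and
        ``unclassifiable``.
    """
    genes = rna.index.intersection(protein.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between the two differential tables")

    def _layer(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if threshold is not None:
            sig = (df.loc[genes, "q"] < threshold).to_numpy(dtype=bool)
        else:
            sig = df.loc[genes, "significant"].to_numpy(dtype=bool)
        return sig, df.loc[genes, "direction"].to_numpy(dtype=object)

    msig, mdir = _layer(rna)
    psig, pdir = _layer(protein)
    groups = np.empty(len(genes), dtype=int)
    flags = np.empty(len(genes), dtype=bool)
    for i in range(len(genes)):
        groups[i], flags[i] = _classify_one(msig[i], mdir[i], psig[i], pdir[i])
    out = pd.DataFrame(
        {
            "group": groups,
            "mrna_sig": msig,
            "prot_sig": psig,
            "mrna_dir": mdir,
            "prot_dir": pdir,
            "unclassifiable": flags,
        },
        index=genes,
    )
    out.index.name = "gene_id"
    return out


def assign_localisation(
    records: pd.DataFrame,
    annotation: Mapping[str, str] | pd.Series,
    default: str | None = None,
) -> pd.DataFrame:
    """Attach the SP/TM/IC/SPTM subcategory to concordance records.

    Unannotated genes take ``default`` when given (the number of fallbacks is
    reported via the ``defaulted`` column), otherwise an error is raised.
    """
    if isinstance(annotation, pd.Series):
        annotation = annotation.to_dict()
    bad = sorted(set(annotation.values()) - set(LOCALISATION_CLASSES))
    if bad:
        raise ValueError(f"unknown localisation classes: {bad}")
    out = records.copy()
    missing = [g for g in out.index if g not in annotation]
    if missing and default is None:
        raise ValueError(f"unannotated genes without default policy: {missing[:10]}")
    out["subcategory"] = [annotation.get(g, default) for g in out.index]
    out["defaulted"] = [g in set(missing) for g in out.index]
    return out


def subcategory_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group subcategory proportions (rows sum to 1)."""
    counts = (
        records.groupby(["group", "subcategory"], observed=True).size().unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def go_crosscheck(
    records: pd.DataFrame, term_membership: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Membership counts per (group, subcategory, term); no statistics."""
    rows = []
    for term, members in term_membership.items():
        members = set(members)
        for (group, sub), sub_df in records.groupby(["group", "subcategory"], observed=True):
            rows.append((group, sub, term, int(sub_df.index.isin(members).sum())))
    return pd.DataFrame(rows, columns=["group", "subcategory", "term", "n_genes"])


@dataclass
class DruggableSummary:
    deregulated: int
    down: int
    up: int
    up_with_ligand: int
    up_with_approved_drug: int


def load_druggable_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the druggability hierarchy: drug => ligand => druggable."""
    required = ["druggable", "has_ligand", "has_approved_drug"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"druggable annotation lacks columns {missing}")
    table = table[required].astype(bool)
    bad = table.index[
        (table["has_approved_drug"] & ~table["has_ligand"])
        | (table["has_ligand"] & ~table["druggable"])
    ]
    if len(bad):
        raise ValueError(f"druggability hierarchy violated for genes: {list(bad[:10])}")
    return table


def druggable_overlap(
    protein_de: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: float = 0.05,
) -> DruggableSummary:
    """Overlap of significantly deregulated proteins with druggable targets.

    ``deregulated`` counts significant druggable proteins, split by
    direction; ligand and approved-drug counts are reported on the
    up-regulated subset.
    """
    annotation = load_druggable_annotation(annotation)
    genes = protein_de.index.intersection(annotation.index)
    sig = (protein_de.loc[genes, "q"] < threshold).to_numpy(dtype=bool)
    direction = protein_de.loc[genes, "direction"].to_numpy(dtype=object)
    druggable = annotation.loc[genes, "druggable"].to_numpy(dtype=bool)
    dereg = sig & druggable
    up = dereg & (direction == "up")
    down = dereg & (direction == "down")
    ligand = annotation.loc[genes, "has_ligand"].to_numpy(dtype=bool)
    drug = annotation.loc[genes, "has_approved_drug"].to_numpy(dtype=bool)
    return DruggableSummary(
        deregulated=int(dereg.sum()),
        down=int(down.sum()),
        up=int(up.sum()),
        up_with_ligand=int((up & ligand).sum()),
        up_with_approved_drug=int((up & drug).sum()),
    )


@dataclass
class ClusterResult:
    """Ward linkage tree: scipy linkage matrix, leaf order and metric."""

    linkage: np.ndarray
    leaf_order: list[int]
    metric: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(matrix: pd.DataFrame | np.ndarray, metric: str = "euclidean") -> ClusterResult:
    """Agglomerative Ward clustering of rows.

    ``metric`` is ``euclidean`` or ``one_minus_pearson``.  Ward linkage on
    the precomputed 1 - Pearson distances follows the Ward.D2 convention on
    those distances (the quantity is not a Euclidean embedding; documented
    behaviour, deterministic given input order).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if metric == "euclidean":
        condensed = pdist(X, metric="euclidean")
    elif metric == "one_minus_pearson":
        if (X.std(axis=1) == 0).any():
            rows = np.flatnonzero(X.std(axis=1) == 0)
            raise ValueError(f"constant rows have undefined Pearson distance: {rows[:10]}")
        corr = np.corrcoef(X)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
    else:
        raise ValueError("metric must be 'euclidean' or 'one_minus_pearson'")
    Z = hierarchy.linkage(condensed, method="ward")
    return ClusterResult(Z, list(hierarchy.leaves_list(Z)), metric)
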