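"""Neoantigen scoring from mutations plus precomputed binding-affinity
tables.

For each protein-altering mutation, candidate peptides of lengths 8-11
(MHC class I) and 15 (class II) containing the altered residue(s) are
enumerated. Per-predictor binding affinities (nM) for each mutant/wild-type
peptide pair are combined as their median (the composite affinity); the
neoepitope ratio is the mutant composite divided by the wild-type
composite. Per mutation, only the best epitope — minimum mutant composite
over all HLA alleles and lengths — is considered, and a mutation is called
neoantigenic when that composite is at or below the binder cutoff (500 nM,
the conventional weak-binder threshold).

Clonality uses a simplified cancer-cell-fraction estimate from allele
fraction, purity and local copy number in place of full purity/ploidy
modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import fisher_association

logger = logging.getLogger(__name__)

CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTHS = (15,)
PEPTIDE_LENGTHS = CLASS_I_LENGTHS + CLASS_II_LENGTHS

DEFAULT_BINDER_CUTOFF_NM = 500.0
DEFAULT_CLONAL_CUTOFF = 0.9


@dataclass(frozen=True)
class PeptidePair:
    """A mutant/wild-type peptide pair for one HLA allele and length."""

    mutation_id: str
    hla_allele: str
    length: int
    mut_peptide: str
    wt_peptide: str | None  # None for novel (frameshift) sequence
    mut_affinities: tuple[float, ...] = ()
    wt_affinities: tuple[float, ...] = ()

    @property
    def mut_median(self) -> float:
        return composite_affinity(self.mut_affinities)

    @property
    def wt_median(self) -> float:
        return composite_affinity(self.wt_affinities)

    @property
    def ratio(self) -> float:
        """Neoepitope ratio: mutant composite / wild-type composite."""
        if self.wt_peptide is not None and self.wt_peptide == self.mut_peptide:
            return 1.0
        wt = self.wt_median
        return self.mut_median / wt if wt and not math.isnan(wt) else float("nan")


@dataclass(frozen=True)
class CcfEstimate:
    mutation_id: str
    ccf: float
    clonal: bool
    uncapped_ccf: float


def enumerate_peptides(
    protein_sequence: str,
    position: int,
    alt_residue: str | None = None,
    novel_suffix: str | None = None,
    mutation_id: str = "",
    hla_allele: str = "",
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
) -> list[PeptidePair]:
    """Enumerate candidate peptide windows for one protein alteration.

    Missense (``alt_residue``): every window of each length containing the
    substituted position; windows running past either protein terminus are
    dropped. Frameshift (``novel_suffix``): the mutant protein is the prefix
    before ``position`` followed by the novel suffix; every window
    containing at least one novel residue is returned with ``wt_peptide``
    absent.
    """
    if (alt_residue is None) == (novel_suffix is None):
        raise ValueError("provide exactly one of alt_residue or novel_suffix")
    n = len(protein_sequence)
    if not (1 <= position <= n):
        raise ValueError(f"position {position} outside protein of length {n}")
    pairs = []
    if alt_residue is not None:
        mut_seq = (
            protein_sequence[: position - 1] + alt_residue + protein_sequence[position:]
        )
        for L in lengths:
            lo = max(1, position - L + 1)
            hi = min(position, n - L + 1)
            for start in range(lo, hi + 1):
                pairs.append(
                    PeptidePair(
                        mutation_id=mutation_id,
                        hla_allele=hla_allele,
                        length=L,
                        mut_peptide=mut_seq[start - 1 : start - 1 + L],
                        wt_peptide=protein_sequence[start - 1 : start - 1 + L],
                    )
                )
    else:
        mut_seq = protein_sequence[: position - 1] + novel_suffix
        m = len(mut_seq)
        first_novel = position
        for L in lengths:
            lo = max(1, first_novel - L + 1)
            hi = m - L + 1
            for start in range(lo, hi + 1):
                pairs.append(
                    PeptidePair(
                        mutation_id=mutation_id,
                        hla_allele=hla_allele,
                        length=L,
                        mut_peptide=mut_seq[start - 1 : start - 1 + L],
                        wt_peptide=None,
                    )
                )
    return pairs


def composite_affinity(values: Sequence[float]) -> float:
    """Median across predictors (mean of the central two for even counts)."""
    if len(values) == 0:
        return float("nan")
    return float(np.median(np.asarray(values, dtype=float)))


def best_epitope(pairs: Sequence[PeptidePair]) -> PeptidePair:
    """The pair with minimum mutant composite affinity across all alleles
    and lengths; ties broken by lower ratio, then lexicographic peptide."""
    if not pairs:
        raise ValueError("no peptide pairs supplied")
    def key(p: PeptidePair):
        r = p.ratio
        return (p.mut_median, r if not math.isnan(r) else math.inf, p.mut_peptide)
    return min(pairs, key=key)


def call_neoantigens(
    pairs_by_mutation: Mapping[str, Sequence[PeptidePair]],
    n_nonsynonymous: int | None = None,
    binder_cutoff_nm: float = DEFAULT_BINDER_CUTOFF_NM,
) -> tuple[dict[str, bool], int, float]:
    """Flag mutations whose best epitope is at or below the binder cutoff.

    Returns (per-mutation flags, neoantigen burden, neoantigenic fraction).
    The fraction's denominator is ``n_nonsynonymous`` when given, else the
    number of mutations with peptide pairs; it is NaN when the denominator
    is zero.
    """
    flags = {
        mid: best_epitope(pairs).mut_median <= binder_cutoff_nm
        for mid, pairs in pairs_by_mutation.items()
        if pairs
    }
    burden = sum(flags.values())
    denom = n_nonsynonymous if n_nonsynonymous is not None else len(flags)
    fraction = burden / denom if denom else float("nan")
    return flags, burden, fraction


def pairs_from_table(affinities: pd.DataFrame) -> dict[str, list[PeptidePair]]:
    """Group a long-format affinity table into PeptidePairs per mutation.

    Expected columns: mutation_id, hla_allele, length, mut_peptide,
    wt_peptide, predictor, mut_nm, wt_nm — one row per predictor.
    """
    required = {
        "mutation_id", "hla_allele", "length", "mut_peptide",
        "wt_peptide", "predictor", "mut_nm", "wt_nm",
    }
    missing = required - set(affinities.columns)
    if missing:
        raise ValueError(f"affinity table missing column(s): {sorted(missing)}")
    out: dict[str, list[PeptidePair]] = {}
    group_cols = ["mutation_id", "hla_allele", "length", "mut_peptide"]
    for (mid, allele, length, mut_pep), grp in affinities.groupby(
        group_cols, sort=True
    ):
        grp = grp.sort_values("predictor")
        wt = grp["wt_peptide"].iloc[0]
        wt_pep = None if pd.isna(wt) or wt in ("", ".") else str(wt)
        out.setdefault(str(mid), []).append(
            PeptidePair(
                mutation_id=str(mid),
                hla_allele=str(allele),
                length=int(length),
                mut_peptide=str(mut_pep),
                wt_peptide=wt_pep,
                mut_affinities=tuple(float(x) for x in grp["mut_nm"]),
                wt_affinities=tuple(float(x) for x in grp["wt_nm"]),
            )
        )
    return out


def estimate_ccf(
    allele_fraction: float,
    purity: float,
    local_cn: int = 2,
    multiplicity: int = 1,
    clonal_cutoff: float = DEFAULT_CLONAL_CUTOFF,
    mutation_id: str = "",
) -> CcfEstimate:
    """Simplified cancer-cell-fraction point estimate.

    ccf = AF x (purity x local_cn + (1 - purity) x 2) / (purity x mult),
    capped at 1.0 (the uncapped value is retained and logged); clonal when
    ccf >= ``clonal_cutoff``.
    """
    if purity <= 0:
        raise ValueError("purity must be > 0")
    raw = allele_fraction * (purity * local_cn + (1 - purity) * 2) / (
        purity * multiplicity
    )
    ccf = min(raw, 1.0)
    if raw > 1.0:
        logger.debug("ccf for %s capped at 1.0 (raw %.3f)", mutation_id or "<?>", raw)
    return CcfEstimate(
        mutation_id=mutation_id,
        ccf=ccf,
        clonal=ccf >= clonal_cutoff,
        uncapped_ccf=raw,
    )


def clonal_neoantigen_contrast(
    neo_flags: Mapping[str, bool], ccfs: Mapping[str, CcfEstimate]
) -> tuple[float, float, float]:
    """Clonal fraction among neoantigenic vs other mutations, with Fisher p.

    Returns (clonal fraction | neoantigenic, clonal fraction | not, p).
    """
    common = sorted(set(neo_flags) & set(ccfs))
    a = b = c = d = 0
    for mid in common:
        clonal = ccfs[mid].clonal
        if neo_flags[mid]:
            a += clonal
            b += not clonal
        else:
            c += clonal
            d += not clonal
    f_neo = a / (a + b) if (a + b) else float("nan")
    f_other = c / (c + d) if (c + d) else float("nan")
    _, p = fisher_association(a, b, c, d)
    return f_neo, f_other, p


def expression_filter(
    expression: pd.DataFrame,
    genes_with_neoantigens: Iterable[str],
    drop_fraction: float = 0.25,
) -> tuple[list[str], float]:
    """Drop the lowest-expressed quartile of genes; report neoantigen overlap.

    Genes are ranked by their mean across samples; the lowest
    ``floor(drop_fraction x G)`` are removed, ties at the cutoff broken by
    gene-name order. Returns (retained genes, fraction of neoantigen genes
    retained).
    """
    if expression.empty:
        raise ValueError("expression matrix is empty")
    means = expression.mean(axis=1)
    order = sorted(means.index, key=lambda g: (means[g], g))
    n_drop = int(math.floor(drop_fraction * len(order)))
    retained = sorted(order[n_drop:])
    neo_genes = set(genes_with_neoantigens)
    if neo_genes:
        overlap = len(neo_genes & set(retained)) / len(neo_genes)
    else:
        overlap = float("nan")
    return retained, overlap
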