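"""Per-sample mutation burden, allelic-fraction statistics, the 6-class
substitution spectrum, and grouped comparisons.

The allelic-fraction filter (drop AF < 0.1) is applied for driver and
recurrence analyses only; burden counts default to unfiltered, with the
filter available behind a flag, since low-AF passengers still contribute to
the mutational load of a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .formats import MutationRecord

logger = logging.getLogger(__name__)

#: Pyrimidine-reference substitution classes, in conventional order.
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class BurdenRow:
    sample_id: str
    n_nonsyn: int
    n_total: int
    mean_af: float
    spectrum: tuple[float, ...]  # fractions over SPECTRUM_CLASSES
    hypermutator: bool = False


def af_filter(
    mutations: Iterable[MutationRecord], min_af: float = 0.1
) -> list[MutationRecord]:
    """Retain mutations with allele fraction >= ``min_af``.

    The boundary is kept: the filter discards fractions *less than* the
    threshold. The number of removed records is logged.
    """
    muts = list(mutations)
    kept = [m for m in muts if m.allele_fraction >= min_af]
    removed = len(muts) - len(kept)
    if removed:
        logger.info("af_filter removed %d/%d records below AF %g",
                    removed, len(muts), min_af)
    return kept


def nonsyn_burden(mutations: Iterable[MutationRecord], sample_id: str) -> int:
    """Count of nonsynonymous coding alterations in one sample."""
    return sum(
        1 for m in mutations if m.sample_id == sample_id and m.is_nonsynonymous
    )


def spectrum_class(ref: str, alt: str) -> str:
    """Collapse an SNV to its pyrimidine-reference substitution class."""
    if ref in "GA":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum6(mutations: Iterable[MutationRecord]) -> tuple[float, ...]:
    """6-class substitution spectrum over SNVs (indels excluded).

    Purine-reference changes are strand-collapsed (G>A counts as C>T, etc.).
    Returns six fractions summing to 1, or all-NaN when there are no SNVs.
    """
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    n = 0
    for m in mutations:
        if not m.is_snv:
            continue
        counts[spectrum_class(m.ref, m.alt)] += 1
        n += 1
    if n == 0:
        return tuple(float("nan") for _ in SPECTRUM_CLASSES)
    return tuple(counts[c] / n for c in SPECTRUM_CLASSES)


def flag_hypermutators(burdens: Sequence[int]) -> list[bool]:
    """Flag samples whose burden exceeds Q3 + 3 x IQR (flagged, never removed)."""
    arr = np.asarray(burdens, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    cut = q3 + 3 * (q3 - q1)
    return [bool(b > cut) for b in arr]


def burden_table(
    mutations: Iterable[MutationRecord],
    apply_af_filter: bool = False,
    min_af: float = 0.1,
) -> list[BurdenRow]:
    """Per-sample burden rows (unfiltered by default; see module docstring)."""
    muts = list(mutations)
    if apply_af_filter:
        muts = af_filter(muts, min_af)
    by_sample: dict[str, list[MutationRecord]] = {}
    for m in muts:
        by_sample.setdefault(m.sample_id, []).append(m)
    rows = []
    for sid in sorted(by_sample):
        sm = by_sample[sid]
        afs = [m.allele_fraction for m in sm]
        rows.append(
            BurdenRow(
                sample_id=sid,
                n_nonsyn=sum(1 for m in sm if m.is_nonsynonymous),
                n_total=len(sm),
                mean_af=float(np.mean(afs)) if afs else float("nan"),
                spectrum=spectrum6(sm),
            )
        )
    flags = flag_hypermutators([r.n_nonsyn for r in rows]) if rows else []
    return [
        BurdenRow(r.sample_id, r.n_nonsyn, r.n_total, r.mean_af, r.spectrum, h)
        for r, h in zip(rows, flags)
    ]


def compare_groups(
    values: Sequence[float], labels: Sequence[int], test: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided two-group comparison of a continuous quantity.

    ``test='t'`` runs Student's t (equal-variance); ``test='wilcoxon'`` runs
    the Wilcoxon rank-sum (Mann-Whitney U). Returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
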