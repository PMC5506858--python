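"""Multi-sample heterogeneity and recurrence phylogenetics.

Within a patient, a somatic event (identified by chrom/pos/ref/alt,
gene-independent) is *ubiquitous* when present in every sample, *shared*
when present in more than one but not all, and *private* when present in
exactly one. Pairwise overlap is Jaccard (intersection over union) by
default; a per-sample-denominator variant is available.

Trees of serial resections are built from mutations powered for detection
in every sample of the patient (binomial model, >= 3 alt reads at the
expected clonal allele fraction), using 1 - Jaccard distances, neighbor
joining, and a germline (all-absent) outgroup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .formats import MutationRecord, SampleMeta
from .assoc import fisher_association

MutationKey = tuple[str, int, str, str]

GERMLINE = "germline"


class UnanalyzablePatientError(ValueError):
    """Raised for patients with fewer than two samples."""


def _keys(sample: Iterable) -> set[MutationKey]:
    out = set()
    for m in sample:
        out.add(m.key if isinstance(m, MutationRecord) else tuple(m))
    return out


@dataclass(frozen=True)
class PatientPartition:
    patient_id: str
    n_ubiquitous: int
    n_shared: int
    n_private: int
    presence: pd.DataFrame  # samples x MutationKeys, boolean

    @property
    def n_total(self) -> int:
        return self.n_ubiquitous + self.n_shared + self.n_private


@dataclass
class PatientTree:
    patient_id: str
    leaves: tuple[str, ...]
    newick: str
    chronology: tuple[str, ...]
    topology_call: str | None = None
    adjacency_score: float | None = None
    tip_distances: pd.DataFrame | None = None


def presence_matrix(
    samples: Mapping[str, Iterable],
) -> pd.DataFrame:
    """Boolean samples-by-events matrix from per-sample mutation sets."""
    keysets = {sid: _keys(muts) for sid, muts in samples.items()}
    all_keys = sorted(set().union(*keysets.values())) if keysets else []
    data = {
        sid: [k in keysets[sid] for k in all_keys] for sid in sorted(keysets)
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=pd.Index(all_keys)
    )


def partition_mutations(
    samples: Mapping[str, Iterable], patient_id: str = ""
) -> PatientPartition:
    """Partition a patient's events into ubiquitous/shared/private."""
    if len(samples) < 2:
        raise UnanalyzablePatientError(
            f"patient {patient_id or '<?>'} has {len(samples)} sample(s); "
            "heterogeneity partitioning needs at least 2"
        )
    pres = presence_matrix(samples)
    k = len(samples)
    counts = pres.sum(axis=0)
    n_ubiq = int((counts == k).sum())
    n_priv = int((counts == 1).sum())
    n_shared = int(((counts > 1) & (counts < k)).sum())
    return PatientPartition(patient_id, n_ubiq, n_shared, n_priv, pres)


def pairwise_shared_fraction(
    sample_a: Iterable, sample_b: Iterable, denominator: str = "union"
) -> float:
    """Fraction of events shared between two samples.

    ``denominator='union'`` gives Jaccard |A∩B|/|A∪B|; ``'per_sample'``
    averages the two directional fractions |A∩B|/|A| and |A∩B|/|B|.
    Two empty samples share fraction NaN.
    """
    a, b = _keys(sample_a), _keys(sample_b)
    inter = len(a & b)
    if denominator == "union":
        union = len(a | b)
        return inter / union if union else float("nan")
    if denominator == "per_sample":
        if not a or not b:
            return float("nan")
        return 0.5 * (inter / len(a) + inter / len(b))
    raise ValueError(f"unknown denominator {denominator!r}")


def per_patient_average(
    samples: Mapping[str, Iterable], denominator: str = "union"
) -> float:
    """Mean shared fraction over all unordered sample pairs of one patient."""
    ids = sorted(samples)
    if len(ids) < 2:
        raise UnanalyzablePatientError("need at least 2 samples")
    vals = [
        pairwise_shared_fraction(samples[i], samples[j], denominator)
        for i, j in itertools.combinations(ids, 2)
    ]
    return float(np.mean(vals))


def discovery_curve(samples: Mapping[str, Iterable]) -> list[float]:
    """Cumulative fraction of the patient's events recovered vs samples used.

    Entry m-1 is the average over all size-m sample subsets of the fraction
    of the patient-wide event union found in the subset union. The curve is
    monotone nondecreasing and ends at 1.
    """
    keysets = [_keys(s) for s in samples.values()]
    k = len(keysets)
    if k == 0:
        return []
    total = set().union(*keysets)
    if not total:
        return [float("nan")] * k
    curve = []
    for m in range(1, k + 1):
        fracs = [
            len(set().union(*combo)) / len(total)
            for combo in itertools.combinations(keysets, m)
        ]
        curve.append(float(np.mean(fracs)))
    return curve


def expected_clonal_af(
    purity: float, local_cn: int = 2, multiplicity: int = 1
) -> float:
    """Expected allele fraction of a clonal single-copy mutation."""
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    return purity * multiplicity / (purity * local_cn + (1 - purity) * 2)


def mutation_detection_power(
    depth: float,
    expected_af: float,
    min_alt_reads: int = 3,
) -> float:
    """P(at least ``min_alt_reads`` alt reads | Binomial(depth, expected AF))."""
    d = int(round(depth))
    if d < 1:
        return 0.0
    return float(stats.binom.sf(min_alt_reads - 1, d, expected_af))


def powered_set(
    presence: pd.DataFrame,
    metas: Mapping[str, SampleMeta],
    power_threshold: float = 0.95,
    local_cn: int = 2,
    multiplicity: int = 1,
    site_depths: Mapping[MutationKey, Mapping[str, float]] | None = None,
) -> list[MutationKey]:
    """Events with detection power >= threshold in *every* sample.

    Power for an event in a sample is evaluated at the site depth when one
    is supplied (``site_depths[key][sample_id]``), otherwise at the sample's
    mean coverage, at the clonal AF implied by the sample's purity. A sample
    missing from ``metas`` is an error directing the user to the metadata
    table.
    """
    for sid in presence.index:
        if sid not in metas:
            raise KeyError(
                f"sample {sid!r} has no metadata row; detection power needs "
                "purity and mean_coverage from the sample metadata TSV"
            )
    afs = {
        sid: expected_clonal_af(metas[sid].purity, local_cn, multiplicity)
        for sid in presence.index
    }
    default_power = {
        sid: mutation_detection_power(metas[sid].mean_coverage, afs[sid])
        for sid in presence.index
    }
    out = []
    for key in presence.columns:
        ok = True
        for sid in presence.index:
            if site_depths is not None and sid in site_depths.get(key, {}):
                pw = mutation_detection_power(site_depths[key][sid], afs[sid])
            else:
                pw = default_power[sid]
            if pw < power_threshold:
                ok = False
                break
        if ok:
            out.append(key)
    return out


def build_tree(
    presence: pd.DataFrame, patient_id: str = "", chronology: Sequence[str] | None = None
) -> PatientTree:
    """Neighbor-joining tree of one patient's samples from 1 - Jaccard
    distances, rooted by an all-absent germline outgroup.

    Negative NJ branch lengths are clamped to 0. Output is invariant to
    sample input order (ids are sorted before the distance matrix is built).
    """
    ids = sorted(presence.index)
    if len(ids) < 2:
        raise UnanalyzablePatientError("need at least 2 samples to build a tree")
    mat = presence.loc[ids].to_numpy(dtype=bool)
    n = len(ids)
    dist = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.sum(mat[i] & mat[j])
            union = np.sum(mat[i] | mat[j])
            d = 1.0 - (inter / union if union else 1.0)
            dist[i, j] = dist[j, i] = d
    for i in range(n):  # germline shares nothing with any sample
        d = 1.0 if mat[i].any() else 0.0
        dist[i, n] = dist[n, i] = d
    all_ids = ids + [GERMLINE]
    tree = nj(DistanceMatrix(dist, all_ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    germ = tree.find(GERMLINE)
    if germ.parent is not None and germ.parent.parent is not None:
        tree = tree.root_at(germ.parent)
    tipdm = tree.tip_tip_distances().to_data_frame()
    tipdm.index = tipdm.index.astype(str)
    tipdm.columns = tipdm.columns.astype(str)
    chron = tuple(chronology) if chronology is not None else tuple(ids)
    pt = PatientTree(
        patient_id=patient_id,
        leaves=tuple(ids),
        newick=str(tree).strip(),
        chronology=chron,
        tip_distances=tipdm,
    )
    call, score = classify_topology(pt)
    pt.topology_call, pt.adjacency_score = call, score
    return pt


def classify_topology(tree: PatientTree) -> tuple[str, float]:
    """Classify a recurrence series as linear or branched evolution.

    For each chronologically consecutive pair (i, i+1), the pair scores when
    sample i+1 is among the nearest *later* samples of i in patristic
    distance — under progressive clonal dominance each resection's closest
    later relative is the next one, while outgrowth from geographically
    distinct lineages scrambles that order. adjacency_score is the fraction
    of consecutive pairs scoring; call = linear when score >= 0.5.
    """
    chron = [s for s in tree.chronology if s in tree.leaves]
    if len(chron) < 2:
        raise UnanalyzablePatientError("need at least 2 samples in chronology")
    dm = tree.tip_distances
    hits = 0
    pairs = 0
    for i in range(len(chron) - 1):
        later = chron[i + 1:]
        dists = {s: dm.loc[chron[i], s] for s in later}
        dmin = min(dists.values())
        nearest = {s for s, d in dists.items() if d <= dmin + 1e-12}
        pairs += 1
        if chron[i + 1] in nearest:
            hits += 1
    score = hits / pairs
    return ("linear" if score >= 0.5 else "branched"), score


def driver_vs_passenger_overlap(
    core_pairs: Sequence[tuple[Iterable[MutationRecord], Iterable[MutationRecord]]],
    driver_genes: Sequence[str],
) -> tuple[tuple[int, int, int, int], float]:
    """Sharing of driver vs passenger mutations across paired assays of the
    same tumor.

    Each pair is two mutation lists from different cores/assays of one
    tumor; every event in their union is shared (seen in both) or not, and
    driver when its gene is in ``driver_genes``. Returns the 2x2 counts
    (driver-shared, driver-unshared, passenger-shared, passenger-unshared)
    and the Fisher two-sided p.
    """
    if not driver_genes:
        raise ValueError("driver gene list is empty")
    genes = set(driver_genes)
    a = b = c = d = 0
    for recs_a, recs_b in core_pairs:
        recs_a, recs_b = list(recs_a), list(recs_b)
        gene_of = {m.key: m.gene for m in recs_a + recs_b}
        keys_a, keys_b = _keys(recs_a), _keys(recs_b)
        for key in keys_a | keys_b:
            shared = key in keys_a and key in keys_b
            if gene_of[key] in genes:
                a += shared
                b += not shared
            else:
                c += shared
                d += not shared
    _, p = fisher_association(a, b, c, d)
    return (a, b, c, d), p
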