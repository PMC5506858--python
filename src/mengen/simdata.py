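"""Synthetic tumor-evolution cohorts with recorded ground truth.

The generator emulates the statistical structure the downstream analyses
assume — clonal phylogenies sampled across regions and serial recurrences,
purity- and depth-driven allele fractions, arm-level copy-number events,
rearrangement junctions with mechanism-dependent microhomology/insertion
features, and lognormal affinity/expression values — so that every stage
can be tested against a known truth table without controlled-access data.

Per patient, a clone tree is grown under an infinite-sites assumption (no
back-mutation, single-copy multiplicity): a trunk clone carries the clonal
mutations and arm events, and subclones extend it either as a single chain
(*linear* evolution: each resection is dominated by a descendant of the
previous dominant clone) or as two sibling chains (*branched*: successive
resections alternate between geographically distinct lineages). A sample's
mutation set is the union along its dominant clone's ancestry; its arm-event
truth is likewise the ancestral union.

Defaults mirror the magnitudes the analyses are anchored to: high-grade
nonsynonymous burden averaging 23, chromosome-22 loss in ~56% of samples
(elevated in NF2-mutant patients so that NF2 mutation and monosomy 22
co-occur), a rearrangement mixture dominated by end joining
(MMEJ 45% / NHEJ 45% / MMBIR 10%), complex events in ~40% of samples, and
two thirds of mutations neoantigenic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import formats
from .formats import (
    JunctionRecord,
    MutationRecord,
    SampleMeta,
    SegmentRecord,
    intrachromosomal_class,
)
from .scna import load_arms

MECHANISMS = ("MMEJ", "NHEJ", "MMBIR")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PREDICTORS = ("NetMHC", "NetMHCpan", "SMM", "SMMPMBEC", "NetMHCIIpan")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_burden_means() -> dict[str, float]:
    return {"I": 8.0, "II": 23.0, "III": 23.0}


def _default_mechanism_mixture() -> dict[str, float]:
    return {"MMEJ": 0.45, "NHEJ": 0.45, "MMBIR": 0.10}


def _default_arm_rates() -> dict[str, tuple[float, float]]:
    # (gain_rate, loss_rate) per arm; unlisted autosomal arms use background
    return {
        "22q": (0.0, 0.56),
        "1p": (0.0, 0.30),
        "6q": (0.0, 0.20),
        "10q": (0.0, 0.18),
        "14q": (0.0, 0.15),
        "18q": (0.0, 0.20),
        "17q": (0.15, 0.0),
        "20q": (0.15, 0.0),
    }


def _default_spectrum() -> dict[str, float]:
    # pyrimidine-reference substitution weights; C>T transitions dominate
    return {"C>A": 0.08, "C>G": 0.06, "C>T": 0.55, "T>A": 0.07, "T>C": 0.16, "T>G": 0.08}


def _default_grade_probs() -> dict[str, float]:
    return {"I": 0.35, "II": 0.5, "III": 0.15}


@dataclass
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions."""

    n_patients: int = 20
    samples_per_patient: int = 2
    clones_per_patient: int = 2
    burden_mean_by_grade: dict[str, float] = field(default_factory=_default_burden_means)
    purity_range: tuple[float, float] = (0.8, 1.0)
    coverage_mean: float = 100.0
    mechanism_mixture: dict[str, float] = field(default_factory=_default_mechanism_mixture)
    complex_event_rate: float = 0.4
    arm_alteration_rates: dict[str, tuple[float, float]] = field(
        default_factory=_default_arm_rates
    )
    arm_background_rate: float = 0.01
    seed: int = 0
    # --- secondary knobs ---
    topology: str = "mixed"  # linear | branched | mixed
    grade_probs: dict[str, float] = field(default_factory=_default_grade_probs)
    spectrum_weights: dict[str, float] = field(default_factory=_default_spectrum)
    nf2_rate: float = 0.5
    canonical_rate_nf2_wt: float = 0.4
    canonical_rate_nf2_mut: float = 0.05
    nf2_chr22_factor: float = 1.5  # 22q-loss multiplier in NF2-mutant patients
    trunk_fraction: float = 0.6  # share of a patient's mutations on the trunk
    mutations_per_clone: int | None = None  # overrides Poisson burden when set
    silent_fraction: float = 0.15  # extra silent/noncoding mutations
    indel_fraction: float = 0.12  # of nonsynonymous mutations
    isolated_junction_mean: dict[str, float] = field(
        default_factory=lambda: {"I": 4.0, "II": 8.0, "III": 10.0}
    )
    complex_size_mean: float = 8.0  # complex size = 4 + Poisson(this)
    neo_binder_rate_trunk: float = 0.70
    neo_binder_rate_subclone: float = 0.60
    binder_cutoff_nm: float = 500.0
    min_alt_reads: int = 3
    subclonal_child_ccf: float = 0.0  # admixture of the dominant clone's child

    def validate(self) -> None:
        if self.n_patients < 1 or self.samples_per_patient < 1:
            raise ConfigError("n_patients and samples_per_patient must be >= 1")
        if self.clones_per_patient < 1:
            raise ConfigError("clones_per_patient must be >= 1")
        if self.samples_per_patient > self.clones_per_patient:
            raise ConfigError(
                "samples_per_patient cannot exceed clones_per_patient "
                "(each resection is dominated by a distinct subclone)"
            )
        total = sum(self.mechanism_mixture.get(m, 0.0) for m in MECHANISMS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mechanism_mixture must sum to 1, got {total}")
        if any(v < 0 for v in self.mechanism_mixture.values()):
            raise ConfigError("mechanism_mixture probabilities must be >= 0")
        for arm, (g, l) in self.arm_alteration_rates.items():
            if g < 0 or l < 0 or g + l > 1:
                raise ConfigError(f"invalid arm rates for {arm}: {(g, l)}")
        if not (0 < self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ConfigError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.topology not in ("linear", "branched", "mixed"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.mutations_per_clone is not None and self.mutations_per_clone < 1:
            raise ConfigError("mutations_per_clone must be >= 1 when set")
        if self.mutations_per_clone is None:
            needed = self.clones_per_patient
            low = min(self.burden_mean_by_grade.values())
            if low < needed:
                raise ConfigError(
                    f"burden mean {low} is below clones_per_patient {needed}: "
                    "clones would outnumber mutations"
                )


@dataclass
class CloneTree:
    clones: list[str]
    parent: dict[str, str | None]  # root's parent is None (germline)
    mutations_per_clone: dict[str, list[str]]  # clone -> mutation ids
    scna_events_per_clone: dict[str, list[tuple[str, str]]]  # (arm, gain|loss)
    truth_topology: str  # linear | branched
    dominant_by_resection: list[str]  # index r-1 -> dominant clone

    def ancestry(self, clone: str) -> list[str]:
        """Clones from root down to (and including) ``clone``."""
        path = []
        cur: str | None = clone
        while cur is not None:
            path.append(cur)
            cur = self.parent[cur]
        return path[::-1]


@dataclass
class SimulatedCohort:
    config: SimConfig
    mutations: list[MutationRecord]
    segments: list[SegmentRecord]
    junctions: list[JunctionRecord]
    metas: list[SampleMeta]
    affinities: pd.DataFrame
    expression: pd.DataFrame
    truth_mutations: pd.DataFrame
    truth_ccf: pd.DataFrame
    truth_arms: pd.DataFrame
    truth_junctions: pd.DataFrame
    truth_patients: pd.DataFrame
    clone_trees: dict[str, CloneTree]


# ---------------------------------------------------------------------------
# Elementary generative operations
# ---------------------------------------------------------------------------

def expected_af(true_ccf: float, purity: float, local_cn: int, multiplicity: int = 1) -> float:
    """Expected allele fraction of a mutation at the given CCF."""
    if local_cn == 0 and true_ccf > 0:
        raise ValueError("local_cn=0 with nonzero CCF")
    denom = purity * local_cn + (1 - purity) * 2
    return true_ccf * purity * multiplicity / denom if denom > 0 else 0.0


def sample_allele_fraction(
    true_ccf: float,
    purity: float,
    local_cn: int,
    depth: int,
    rng: np.random.Generator,
    multiplicity: int = 1,
) -> tuple[int, int]:
    """Draw (t_alt_count, t_depth) for one mutation in one sample.

    Depth is Poisson around the nominal value (min 1); the alt count is
    binomial at the expected allele fraction.
    """
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    af = expected_af(true_ccf, purity, local_cn, multiplicity)
    t_depth = max(1, int(rng.poisson(depth)))
    t_alt = int(rng.binomial(t_depth, af))
    return t_alt, t_depth


def simulate_junction(mechanism: str, rng: np.random.Generator) -> tuple[int, int]:
    """Draw (homology_len, insertion_len) for a junction of one mechanism.

    MMEJ: 3-20 bp microhomology, no insertion. NHEJ: blunt-ish, 0-2 bp
    homology or a short (< 10 bp) untemplated insertion. MMBIR: a templated
    insertion of at least 10 bp.
    """
    if mechanism == "MMEJ":
        return int(rng.integers(3, 21)), 0
    if mechanism == "NHEJ":
        if rng.random() < 0.5:
            return int(rng.integers(0, 3)), 0
        return 0, int(rng.integers(0, 10))
    if mechanism == "MMBIR":
        return 0, int(rng.integers(10, 51))
    raise ValueError(f"unknown mechanism {mechanism!r}")


def _draw_substitution(rng: np.random.Generator, weights: Mapping[str, float]) -> tuple[str, str]:
    classes = sorted(weights)
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    cls = classes[int(rng.choice(len(classes), p=probs))]
    ref, alt = cls.split(">")
    if rng.random() < 0.5:  # report on the purine strand half the time
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
    return ref, alt


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _build_clone_tree(
    rng: np.random.Generator, config: SimConfig, topology: str, pid: str
) -> CloneTree:
    k = config.clones_per_patient
    clones = [f"{pid}_c{i}" for i in range(1, k + 2)]  # trunk + k subclones
    trunk = clones[0]
    parent: dict[str, str | None] = {trunk: None}
    subs = clones[1:]
    if topology == "linear" or k == 1:
        prev = trunk
        for c in subs:
            parent[c] = prev
            prev = c
        dominants = subs
    else:
        half = (k + 1) // 2
        branch_a, branch_b = subs[:half], subs[half:]
        for branch in (branch_a, branch_b):
            prev = trunk
            for c in branch:
                parent[c] = prev
                prev = c
        # successive resections alternate between the two sibling lineages
        dominants = []
        ia = ib = 0
        for r in range(k):
            if (r % 2 == 0 and ia < len(branch_a)) or ib >= len(branch_b):
                dominants.append(branch_a[ia]); ia += 1
            else:
                dominants.append(branch_b[ib]); ib += 1
    return CloneTree(
        clones=clones,
        parent=parent,
        mutations_per_clone={c: [] for c in clones},
        scna_events_per_clone={c: [] for c in clones},
        truth_topology=topology if k > 1 else "linear",
        dominant_by_resection=dominants[: config.samples_per_patient],
    )


def _classification(rng: np.random.Generator, config: SimConfig, nonsyn: bool) -> str:
    if not nonsyn:
        return "silent" if rng.random() < 0.7 else "noncoding"
    if rng.random() < config.indel_fraction:
        return "frameshift_indel" if rng.random() < 0.7 else "inframe_indel"
    r = rng.random()
    if r < 0.80:
        return "missense"
    if r < 0.90:
        return "nonsense"
    return "splice_site"


_INACTIVATING = ("frameshift_indel", "splice_site", "nonsense")


def simulate_cohort(config: SimConfig, outdir: str | Path | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``.

    When ``outdir`` is given, all standard-format files (mutation TSV, SEG,
    BEDPE, metadata TSV, affinity and expression TSVs) and the truth tables
    are written there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    arms = [a for a in load_arms() if a.chrom in formats.AUTOSOMES]
    arm_by_name = {a.name: a for a in arms}

    mutations: list[MutationRecord] = []
    segments: list[SegmentRecord] = []
    junctions: list[JunctionRecord] = []
    metas: list[SampleMeta] = []
    aff_rows: list[dict] = []
    truth_mut_rows: list[dict] = []
    truth_ccf_rows: list[dict] = []
    truth_arm_rows: list[dict] = []
    truth_junc_rows: list[dict] = []
    truth_pat_rows: list[dict] = []
    clone_trees: dict[str, CloneTree] = {}
    mutated_genes: list[str] = []

    grade_names = sorted(config.grade_probs)
    grade_p = np.array([config.grade_probs[g] for g in grade_names], dtype=float)
    grade_p /= grade_p.sum()

    for pi in range(config.n_patients):
        pid = f"P{pi + 1:03d}"
        grade = grade_names[int(rng.choice(len(grade_names), p=grade_p))]
        r = rng.random()
        histology = "angiomatous" if r < 0.08 else ("rhabdoid" if r < 0.15 else "atypical")
        r = rng.random()
        radiation = (
            "radiation_induced" if r < 0.15
            else ("post_adjuvant_RT" if r < 0.30 else "naive")
        )
        nf2_mutant = rng.random() < config.nf2_rate
        canonical_rate = (
            config.canonical_rate_nf2_mut if nf2_mutant else config.canonical_rate_nf2_wt
        )
        canonical = rng.random() < canonical_rate

        topology = config.topology
        if topology == "mixed":
            topology = "linear" if rng.random() < 0.5 else "branched"
        tree = _build_clone_tree(rng, config, topology, pid)
        trunk = tree.clones[0]

        # --- arm events: trunk-dominated (SCNAs precede most mutations) ---
        for arm in arms:
            g_rate, l_rate = config.arm_alteration_rates.get(
                arm.name, (config.arm_background_rate, config.arm_background_rate)
            )
            if histology == "angiomatous":
                g_rate, l_rate = max(g_rate, 0.4), min(l_rate, 0.02)
            elif arm.name == "22q":
                f = config.nf2_chr22_factor
                l_rate = min(1.0, l_rate * (f if nf2_mutant else 2 - f))
            r = rng.random()
            if r < g_rate:
                tree.scna_events_per_clone[trunk].append((arm.name, "gain"))
            elif r < g_rate + l_rate:
                tree.scna_events_per_clone[trunk].append((arm.name, "loss"))
        # occasional private subclonal arm events
        for clone in tree.clones[1:]:
            if rng.random() < 0.15:
                arm = arms[int(rng.integers(len(arms)))]
                taken = {a for c in tree.clones for a, _ in tree.scna_events_per_clone[c]}
                if arm.name not in taken:
                    ev = "loss" if rng.random() < 0.7 else "gain"
                    tree.scna_events_per_clone[clone].append((arm.name, ev))

        # --- mutations assigned to clones ---
        if config.mutations_per_clone is not None:
            counts = {c: config.mutations_per_clone for c in tree.clones}
        else:
            total = int(rng.poisson(config.burden_mean_by_grade[grade]))
            total = max(total, 1)
            n_trunk = int(round(config.trunk_fraction * total))
            n_sub = total - n_trunk
            counts = {trunk: n_trunk}
            subs = tree.clones[1:]
            if subs:
                base, extra = divmod(n_sub, len(subs))
                for i, c in enumerate(subs):
                    counts[c] = base + (1 if i < extra else 0)
            elif n_sub:
                counts[trunk] += n_sub

        used_keys: set[tuple] = set()
        mut_index = 0
        driver_plan: list[tuple[str, str]] = []
        if nf2_mutant:
            cls = (
                _INACTIVATING[int(rng.integers(3))]
                if rng.random() < 0.89 else "missense"
            )
            driver_plan.append(("NF2", cls))
        if canonical:
            gene = ("TRAF7", "KLF4", "AKT1", "SMO")[int(rng.integers(4))]
            driver_plan.append((gene, "missense"))

        for clone in tree.clones:
            n_nonsyn = counts.get(clone, 0)
            n_silent = int(rng.poisson(config.silent_fraction * n_nonsyn))
            for j in range(n_nonsyn + n_silent):
                nonsyn = j < n_nonsyn
                if clone == trunk and driver_plan:
                    gene, cls = driver_plan.pop()
                    nonsyn = True
                else:
                    gene = f"G{int(rng.integers(1, 5000)):04d}"
                    cls = _classification(rng, config, nonsyn)
                is_indel = cls in ("frameshift_indel", "inframe_indel")
                while True:
                    chrom = str(int(rng.integers(1, 23)))
                    pos = int(rng.integers(1_000_000, 120_000_000))
                    if is_indel:
                        if rng.random() < 0.6:  # deletion
                            ref = "".join(
                                "ACGT"[int(x)]
                                for x in rng.integers(0, 4, int(rng.integers(2, 6)))
                            )
                            alt = ref[0]
                        else:
                            alt_s = "".join(
                                "ACGT"[int(x)]
                                for x in rng.integers(0, 4, int(rng.integers(2, 6)))
                            )
                            ref, alt = alt_s[0], alt_s
                    else:
                        ref, alt = _draw_substitution(rng, config.spectrum_weights)
                    key = (chrom, pos, ref, alt)
                    if key not in used_keys:
                        used_keys.add(key)
                        break
                mut_index += 1
                mid = f"{pid}_m{mut_index:04d}"
                tree.mutations_per_clone[clone].append(mid)
                is_trunk = clone == trunk
                binder_rate = (
                    config.neo_binder_rate_trunk if is_trunk
                    else config.neo_binder_rate_subclone
                )
                neoantigen = bool(rng.random() < binder_rate) and nonsyn
                truth_mut_rows.append(
                    {
                        "mutation_id": mid,
                        "patient_id": pid,
                        "clone": clone,
                        "gene": gene,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "classification": cls,
                        "nonsynonymous": nonsyn,
                        "neoantigen": neoantigen,
                    }
                )
                if neoantigen or nonsyn:
                    _make_affinity_rows(rng, mid, neoantigen, config, aff_rows)
                mutated_genes.append(gene)

        # --- samples ---
        purity_lo, purity_hi = config.purity_range
        mut_truth_patient = [r for r in truth_mut_rows if r["patient_id"] == pid]
        mut_by_id = {r["mutation_id"]: r for r in mut_truth_patient}
        clone_of = {r["mutation_id"]: r["clone"] for r in mut_truth_patient}
        for si in range(config.samples_per_patient):
            sid = f"{pid}_S{si + 1}"
            purity = float(rng.uniform(purity_lo, purity_hi))
            coverage = float(config.coverage_mean)
            metas.append(
                SampleMeta(
                    sample_id=sid,
                    patient_id=pid,
                    resection_index=si + 1,
                    grade=grade,
                    histology=histology,
                    radiation_status=radiation,
                    purity=purity,
                    ploidy=2.0,
                    mean_coverage=coverage,
                )
            )
            dominant = tree.dominant_by_resection[si]
            ancestry = set(tree.ancestry(dominant))
            children = [c for c, p in tree.parent.items() if p == dominant]
            subclonal = set(children[:1]) if config.subclonal_child_ccf > 0 else set()

            # arm-event truth and segments
            events: dict[str, str] = {}
            for clone in tree.ancestry(dominant):
                for arm_name, ev in tree.scna_events_per_clone[clone]:
                    events[arm_name] = ev
            for arm_name, ev in sorted(events.items()):
                truth_arm_rows.append({"sample_id": sid, "arm": arm_name, "event": ev})
            for arm in arms:
                ev = events.get(arm.name)
                if ev == "gain":
                    base = float(np.log2(1 + purity / 2))
                elif ev == "loss":
                    base = float(np.log2(1 - purity / 2))
                else:
                    base = 0.0
                n_seg = int(rng.integers(1, 4))
                cuts = np.sort(rng.integers(arm.start + 1, arm.end, n_seg - 1)) if n_seg > 1 else np.array([], dtype=int)
                bounds = [arm.start, *[int(c) for c in cuts], arm.end + 1]
                for b0, b1 in zip(bounds[:-1], bounds[1:]):
                    if b1 <= b0:
                        continue
                    segments.append(
                        SegmentRecord(
                            sample_id=sid,
                            chrom=arm.chrom,
                            start=b0,
                            end=b1 - 1,
                            n_probes=max(10, (b1 - b0) // 100_000),
                            log2_ratio=base + float(rng.normal(0, 0.03)),
                        )
                    )

            # mutation calls with purity/depth-driven allele fractions
            for mid, row in mut_by_id.items():
                clone = clone_of[mid]
                if clone in ancestry:
                    ccf = 1.0
                elif clone in subclonal:
                    ccf = config.subclonal_child_ccf
                else:
                    ccf = 0.0
                truth_ccf_rows.append(
                    {"mutation_id": mid, "sample_id": sid, "true_ccf": ccf}
                )
                if ccf == 0.0:
                    continue
                t_alt, t_depth = sample_allele_fraction(
                    ccf, purity, 2, int(coverage), rng
                )
                if t_alt >= config.min_alt_reads:
                    mutations.append(
                        MutationRecord(
                            sample_id=sid,
                            patient_id=pid,
                            gene=row["gene"],
                            chrom=row["chrom"],
                            pos=row["pos"],
                            ref=row["ref"],
                            alt=row["alt"],
                            classification=row["classification"],
                            t_alt_count=t_alt,
                            t_depth=t_depth,
                        )
                    )

            # rearrangement junctions
            _simulate_sample_junctions(
                rng, config, sid, grade, junctions, truth_junc_rows
            )

        clone_trees[pid] = tree
        truth_pat_rows.append(
            {
                "patient_id": pid,
                "grade": grade,
                "histology": histology,
                "radiation_status": radiation,
                "topology": tree.truth_topology,
                "nf2_mutant": nf2_mutant,
                "canonical_non_nf2": canonical,
                "chr22_loss": any(
                    a == "22q" and e == "loss"
                    for c in tree.clones
                    for a, e in tree.scna_events_per_clone[c]
                ),
            }
        )

    # --- expression matrix: mutated genes plus background, lognormal ---
    genes = sorted(set(mutated_genes) | {f"BG{i:04d}" for i in range(200)})
    n_expr_samples = min(20, max(4, config.n_patients))
    expr = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=1.5, size=(len(genes), n_expr_samples)),
        index=pd.Index(genes, name="gene"),
        columns=[f"EXPR{j + 1}" for j in range(n_expr_samples)],
    )

    cohort = SimulatedCohort(
        config=config,
        mutations=mutations,
        segments=segments,
        junctions=junctions,
        metas=metas,
        affinities=pd.DataFrame(
            aff_rows,
            columns=[
                "mutation_id", "hla_allele", "length", "mut_peptide",
                "wt_peptide", "predictor", "mut_nm", "wt_nm",
            ],
        ),
        expression=expr,
        truth_mutations=pd.DataFrame(truth_mut_rows),
        truth_ccf=pd.DataFrame(truth_ccf_rows),
        truth_arms=pd.DataFrame(truth_arm_rows, columns=["sample_id", "arm", "event"]),
        truth_junctions=pd.DataFrame(
            truth_junc_rows,
            columns=["sample_id", "junction_index", "mechanism", "event_id", "complex"],
        ),
        truth_patients=pd.DataFrame(truth_pat_rows),
        clone_trees=clone_trees,
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def _make_affinity_rows(rng, mid, neoantigen, config, aff_rows):
    """Fabricate lognormal per-predictor affinities for one mutation.

    Several candidate pairs across HLA alleles and lengths; exactly when the
    mutation is a true binder does the best pair's mutant composite fall at
    or below the binder cutoff.
    """
    n_pairs = 4
    best = int(rng.integers(n_pairs))
    cutoff = config.binder_cutoff_nm
    for k in range(n_pairs):
        allele = f"HLA-A*{int(rng.integers(1, 33)):02d}:01"
        length = (8, 9, 10, 11, 15)[int(rng.integers(5))]
        mut_pep = "".join(AMINO_ACIDS[int(x)] for x in rng.integers(0, 20, length))
        wt_pep = mut_pep[: length // 2] + AMINO_ACIDS[int(rng.integers(20))] + mut_pep[length // 2 + 1 :]
        if neoantigen and k == best:
            target = float(np.exp(rng.uniform(np.log(20), np.log(cutoff * 0.98))))
        else:
            target = float(np.exp(rng.uniform(np.log(cutoff * 1.05), np.log(30_000))))
        wt_target = float(np.exp(rng.uniform(np.log(200), np.log(20_000))))
        mut_vals = target * np.exp(rng.normal(0, 0.4, len(PREDICTORS)))
        mut_vals *= target / np.median(mut_vals)
        wt_vals = wt_target * np.exp(rng.normal(0, 0.4, len(PREDICTORS)))
        wt_vals *= wt_target / np.median(wt_vals)
        for pred, mv, wv in zip(PREDICTORS, mut_vals, wt_vals):
            aff_rows.append(
                {
                    "mutation_id": mid,
                    "hla_allele": allele,
                    "length": length,
                    "mut_peptide": mut_pep,
                    "wt_peptide": wt_pep,
                    "predictor": pred,
                    "mut_nm": float(mv),
                    "wt_nm": float(wv),
                }
            )


def _simulate_sample_junctions(rng, config, sid, grade, junctions, truth_rows):
    """Isolated junctions far apart plus (sometimes) one clustered complex
    event whose breakends chain within the link window."""
    mech_names = MECHANISMS
    mech_p = np.array([config.mechanism_mixture.get(m, 0.0) for m in mech_names])
    mech_p = mech_p / mech_p.sum()

    def draw_mech():
        return mech_names[int(rng.choice(len(mech_names), p=mech_p))]

    event_counter = 0
    jx_index = 0
    # isolated events on a coarse grid, >= 10 Mb apart
    n_iso = int(rng.poisson(config.isolated_junction_mean.get(grade, 6.0)))
    used_slots: set[tuple[str, int]] = set()

    def fresh_pos(chrom):
        for _ in range(50):
            slot = int(rng.integers(0, 11))
            if (chrom, slot) not in used_slots:
                used_slots.add((chrom, slot))
                return 5_000_000 + slot * 10_000_000 + int(rng.integers(0, 5000))
        return int(rng.integers(5_000_000, 115_000_000))

    def add_junction(chromA, posA, strandA, chromB, posB, strandB, event_id, is_complex):
        nonlocal jx_index
        mech = draw_mech()
        hom, ins = simulate_junction(mech, rng)
        if chromA != chromB:
            sv_class = "translocation"
        else:
            sv_class = intrachromosomal_class(strandA, strandB)
        junctions.append(
            JunctionRecord(
                sample_id=sid,
                chromA=chromA, posA=posA, strandA=strandA,
                chromB=chromB, posB=posB, strandB=strandB,
                sv_class=sv_class,
                homology_len=hom,
                insertion_len=ins,
                repeatA=bool(rng.random() < 0.2),
                repeatB=bool(rng.random() < 0.2),
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "junction_index": jx_index,
                "mechanism": mech,
                "event_id": event_id,
                "complex": is_complex,
            }
        )
        jx_index += 1

    for _ in range(n_iso):
        event_counter += 1
        eid = f"{sid}_e{event_counter}"
        if rng.random() < 0.21:  # isolated translocation
            ca, cb = rng.choice(22, size=2, replace=False) + 1
            ca, cb = str(int(ca)), str(int(cb))
            add_junction(
                ca, fresh_pos(ca), "+-"[int(rng.integers(2))],
                cb, fresh_pos(cb), "+-"[int(rng.integers(2))],
                eid, False,
            )
        else:
            c = str(int(rng.integers(1, 23)))
            p = fresh_pos(c)
            # intrachromosomal class mix: deletions most common, then
            # inversions, then duplications
            strand_pairs = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
            sA, sB = strand_pairs[
                int(rng.choice(4, p=[0.45, 0.19, 0.18, 0.18]))
            ]
            add_junction(c, p, sA, c, p + int(rng.integers(20_000, 900_000)), sB, eid, False)

    if rng.random() < config.complex_event_rate:
        event_counter += 1
        eid = f"{sid}_e{event_counter}"
        size = 4 + int(rng.poisson(config.complex_size_mean))
        n_chroms = min(1 + int(rng.poisson(3)), 7)
        chroms = [str(int(c) + 1) for c in rng.choice(22, size=n_chroms, replace=False)]
        # chained breakend positions per chromosome, gaps below the window
        next_pos = {}
        for c in chroms:
            slot = int(rng.integers(0, 11))
            for _ in range(50):
                if (c, slot) not in used_slots:
                    break
                slot = int(rng.integers(0, 11))
            used_slots.add((c, slot))
            next_pos[c] = 5_000_000 + slot * 10_000_000

        def chained_pos(c):
            p = next_pos[c]
            next_pos[c] = p + int(rng.integers(1_000, 8_000))
            return p

        for j in range(size):
            if n_chroms == 1 or rng.random() < 0.3:
                c = chroms[j % n_chroms]
                pA, pB = chained_pos(c), chained_pos(c)
                add_junction(
                    c, pA, "+-"[int(rng.integers(2))],
                    c, pB, "+-"[int(rng.integers(2))],
                    eid, True,
                )
            else:
                ca = chroms[j % n_chroms]
                cb = chroms[(j + 1) % n_chroms]
                add_junction(
                    ca, chained_pos(ca), "+-"[int(rng.integers(2))],
                    cb, chained_pos(cb), "+-"[int(rng.integers(2))],
                    eid, True,
                )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "segments": outdir / "segments.seg",
        "junctions": outdir / "junctions.bedpe",
        "metadata": outdir / "samples.tsv",
        "affinities": outdir / "affinities.tsv",
        "expression": outdir / "expression.tsv",
        "truth_mutations": outdir / "truth_mutations.tsv",
        "truth_ccf": outdir / "truth_ccf.tsv",
        "truth_arms": outdir / "truth_arms.tsv",
        "truth_junctions": outdir / "truth_junctions.tsv",
        "truth_patients": outdir / "truth_patients.tsv",
    }
    formats.write_mutations(cohort.mutations, paths["mutations"])
    formats.write_segments(cohort.segments, paths["segments"])
    formats.write_junctions(cohort.junctions, paths["junctions"])
    formats.write_sample_meta(cohort.metas, paths["metadata"])
    cohort.affinities.to_csv(paths["affinities"], sep="\t", index=False)
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.truth_mutations.to_csv(paths["truth_mutations"], sep="\t", index=False)
    cohort.truth_ccf.to_csv(paths["truth_ccf"], sep="\t", index=False)
    cohort.truth_arms.to_csv(paths["truth_arms"], sep="\t", index=False)
    cohort.truth_junctions.to_csv(paths["truth_junctions"], sep="\t", index=False)
    cohort.truth_patients.to_csv(paths["truth_patients"], sep="\t", index=False)
    return paths


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a ``key = value`` text file.

    Scalar fields are parsed by type; dict-valued fields accept
    ``key:value`` pairs separated by commas, e.g.
    ``mechanism_mixture = MMEJ:0.5, NHEJ:0.4, MMBIR:0.1``.
    """
    cfg = SimConfig()
    field_types = {f.name: f for f in dataclasses.fields(SimConfig)}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in field_types:
                raise ConfigError(f"line {lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                d = {}
                for item in val.split(","):
                    k, v = (s.strip() for s in item.split(":", 1))
                    old = next(iter(current.values())) if current else 0.0
                    d[k] = type(old)(_parse_scalar(v)) if not isinstance(old, tuple) else tuple(
                        float(x) for x in v.split("/")
                    )
                setattr(cfg, key, d)
            elif isinstance(current, tuple):
                setattr(cfg, key, tuple(float(x) for x in val.split(",")))
            elif isinstance(current, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(val))
            elif isinstance(current, float):
                setattr(cfg, key, float(val))
            elif current is None or isinstance(current, str):
                setattr(cfg, key, val if val.lower() != "none" else None)
    cfg.validate()
    return cfg


def _parse_scalar(v: str):
    try:
        return float(v)
    except ValueError:
        return v
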