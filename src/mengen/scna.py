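"""Arm-level copy-number analysis: percent genome disrupted, arm-event
calling, cohort incidence, and chromosome-22-loss detection.

Calling conventions: a segment is *altered* when ``|log2_ratio| >=
amp_threshold`` (default 0.2, a conventional arm-call cut); an arm is called
gained (lost) when at least ``frac_threshold`` (default 0.8) of its covered
length is altered in the corresponding direction. Sex chromosomes are
excluded from the disruption metric because cohorts mix sexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .formats import AUTOSOMES, SegmentRecord, _chrom_sort_key


@dataclass(frozen=True)
class ArmDefinition:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ArmCall:
    sample_id: str
    arm: ArmDefinition
    call: str  # gain | loss | neutral
    altered_fraction: float


def load_arms(path=None) -> list[ArmDefinition]:
    """Load chromosome-arm coordinates (default: bundled hg19 table)."""
    if path is None:
        ref = resources.files("mengen.data") / "arms_hg19.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    arms = [
        ArmDefinition(str(r.chrom), str(r.arm), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    arms.sort(key=lambda a: (_chrom_sort_key(a.chrom), a.arm))
    return arms


def percent_genome_disrupted(
    segments: Iterable[SegmentRecord], amp_threshold: float = 0.2
) -> float:
    """Percent of covered autosomal length on copy-number-altered segments.

    100 x (summed length of autosomal segments with |log2| >= threshold)
    over the summed length of all autosomal segments.
    """
    total = 0
    altered = 0
    for seg in segments:
        if seg.chrom not in AUTOSOMES:
            continue
        total += seg.length
        if abs(seg.log2_ratio) >= amp_threshold:
            altered += seg.length
    if total == 0:
        raise ValueError("no autosomal segment coverage; cannot compute disruption")
    return 100.0 * altered / total


def call_arm_events(
    segments: Iterable[SegmentRecord],
    arms: Sequence[ArmDefinition],
    amp_threshold: float = 0.2,
    frac_threshold: float = 0.8,
) -> list[ArmCall]:
    """Call per-arm gain/loss for one sample's segments.

    The altered fraction of an arm is computed over the arm length covered by
    segments; arms with no coverage are skipped.
    """
    segs = list(segments)
    sample_ids = {s.sample_id for s in segs}
    if len(sample_ids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(sample_ids)}")
    calls = []
    for arm in arms:
        covered = gained = lost = 0
        for seg in segs:
            if seg.chrom != arm.chrom:
                continue
            ov = min(seg.end, arm.end) - max(seg.start, arm.start) + 1
            if ov <= 0:
                continue
            covered += ov
            if seg.log2_ratio >= amp_threshold:
                gained += ov
            elif seg.log2_ratio <= -amp_threshold:
                lost += ov
        if covered == 0:
            continue
        gain_frac = gained / covered
        loss_frac = lost / covered
        if gain_frac >= frac_threshold:
            call, frac = "gain", gain_frac
        elif loss_frac >= frac_threshold:
            call, frac = "loss", loss_frac
        else:
            call, frac = "neutral", (gained + lost) / covered
        calls.append(
            ArmCall(sample_id=segs[0].sample_id if segs else "", arm=arm,
                    call=call, altered_fraction=frac)
        )
    return calls


def chr22_loss(arm_calls: Iterable[ArmCall]) -> bool:
    """True iff the sample's 22q arm is called lost."""
    for c in arm_calls:
        if c.arm.name == "22q" and c.call == "loss":
            return True
    return False


def arm_incidence(
    cohort_calls: dict[str, list[ArmCall]],
    sample_histology: dict[str, str] | None = None,
    exclude_histology: set[str] = frozenset({"angiomatous"}),
) -> pd.DataFrame:
    """Per-arm gain/loss incidence (%) across a cohort.

    Samples whose histology is in ``exclude_histology`` (by default the
    angiomatous subtype, whose gain-dominated profile is an outlier) are
    excluded from the denominator. Rows are ordered by genome position.
    """
    if sample_histology is None:
        sample_histology = {}
    kept = [
        sid
        for sid in cohort_calls
        if sample_histology.get(sid, "") not in exclude_histology
    ]
    if not kept:
        raise ValueError("no samples left after histology exclusion")
    counts: dict[str, dict[str, int]] = {}
    arms_seen: dict[str, ArmDefinition] = {}
    for sid in kept:
        for c in cohort_calls[sid]:
            arms_seen[c.arm.name] = c.arm
            d = counts.setdefault(c.arm.name, {"gain": 0, "loss": 0, "n": 0})
            d["n"] += 1
            if c.call in ("gain", "loss"):
                d[c.call] += 1
    rows = []
    for name, arm in sorted(
        arms_seen.items(), key=lambda kv: (_chrom_sort_key(kv[1].chrom), kv[1].arm)
    ):
        d = counts[name]
        rows.append(
            {
                "arm": name,
                "n_samples": d["n"],
                "gain_pct": 100.0 * d["gain"] / d["n"],
                "loss_pct": 100.0 * d["loss"] / d["n"],
            }
        )
    return pd.DataFrame(rows)
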