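"""Dataset partitioning for the priming and rehearsal training stages.

Priming: the prior data (high-prevalence + healthy cohorts) is split
80–20 train/validation at the *site* level, stratified by the three-way
referral decision.

Rehearsal: prior sites keep their priming partition, except that
contralateral-normal sites of lesion patients are dropped; every
new-study (low-prevalence) referral site goes to the holdout test set, with
patient grouping dominating (a referred patient's other sites follow to
test); the remaining new-study patients are allocated as whole blocks across
train/validation/test so that the overall partition sizes meet the target
proportions.  Block allocation is solved exactly by dynamic programming over
seeded-shuffled patient blocks (greedy fallback when no exact packing
exists), so re-running with one seed reproduces the assignment bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import SiteRecord

PARTITIONS = ("train", "validation", "test")

DEFAULT_TARGET_FRACTIONS = (0.52, 0.13, 0.35)


@dataclass
class SplitAssignment:
    """site_id → partition mapping plus per-site provenance notes."""

    stage: str                      # "priming" | "rehearsal"
    mapping: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    @property
    def dropped(self) -> list[str]:
        return [sid for sid, note in self.notes.items() if note == "dropped_contralateral"]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"site_id": sid, "partition": part, "note": self.notes.get(sid, "")}
            for sid, part in sorted(self.mapping.items())
        ]
        rows += [
            {"site_id": sid, "partition": "dropped", "note": "dropped_contralateral"}
            for sid in sorted(self.dropped)
        ]
        pd.DataFrame(rows, columns=["site_id", "partition", "note"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, stage: str = "", seed: int = 0) -> "SplitAssignment":
        df = pd.read_csv(path, keep_default_na=False)
        out = cls(stage=stage, seed=seed)
        for _, row in df.iterrows():
            if row["partition"] == "dropped":
                out.notes[row["site_id"]] = "dropped_contralateral"
            else:
                out.mapping[row["site_id"]] = row["partition"]
                if row["note"]:
                    out.notes[row["site_id"]] = row["note"]
        return out


def priming_split(
    prior_sites: Sequence[SiteRecord], ratio: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Site-level stratified train/validation split of the prior data."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must lie in (0, 1]")
    bad = [s.site_id for s in prior_sites if s.cohort == "low_prevalence"]
    if bad:
        raise ValueError(f"priming split accepts prior cohorts only; got low-prevalence {bad[:3]}")
    rng = np.random.default_rng(seed)
    out = SplitAssignment(stage="priming", seed=seed, params={"ratio": ratio})
    strata: dict[str, list[str]] = {}
    for s in prior_sites:
        strata.setdefault(s.referral_label, []).append(s.site_id)
    for label in sorted(strata):
        ids = sorted(strata[label])
        if len(ids) < 2:
            warnings.warn(f"stratum {label!r} has {len(ids)} site(s); assigning all to train")
            for sid in ids:
                out.mapping[sid] = "train"
            continue
        order = rng.permutation(len(ids))
        n_train = int(round(ratio * len(ids)))
        for k, j in enumerate(order):
            out.mapping[ids[j]] = "train" if k < n_train else "validation"
    return out


def _integer_targets(fractions: Sequence[float], total: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` by ``fractions``."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    for idx in np.argsort(-(raw - base))[: total - base.sum()]:
        base[idx] += 1
    return base.tolist()


def _exact_block_assignment(
    blocks: list[tuple[str, int]],
    q_train: int,
    q_val: int,
    rng: np.random.Generator,
) -> Optional[dict[str, str]]:
    """Assign whole blocks so train/validation quotas are met exactly.

    Suffix-feasibility DP over the (shuffled) block list; the forward walk
    picks uniformly among feasible partition choices per block, so the
    realized assignment is random but quota-exact.  Returns None when no
    exact packing exists.
    """
    n = len(blocks)
    feas = [None] * (n + 1)
    f = np.zeros((q_train + 1, q_val + 1), dtype=bool)
    f[0, 0] = True
    feas[n] = f
    for i in range(n - 1, -1, -1):
        s = blocks[i][1]
        nxt = feas[i + 1]
        f = nxt.copy()  # block -> test
        if s <= q_train:
            f[s:, :] |= nxt[:-s, :]
        if s <= q_val:
            f[:, s:] |= nxt[:, :-s]
        feas[i] = f
    if not feas[0][q_train, q_val]:
        return None
    out: dict[str, str] = {}
    a, b = q_train, q_val
    for i, (pid, s) in enumerate(blocks):
        options = []
        if a >= s and feas[i + 1][a - s, b]:
            options.append("train")
        if b >= s and feas[i + 1][a, b - s]:
            options.append("validation")
        if feas[i + 1][a, b]:
            options.append("test")
        choice = options[int(rng.integers(len(options)))]
        out[pid] = choice
        if choice == "train":
            a -= s
        elif choice == "validation":
            b -= s
    return out


def _greedy_block_assignment(
    blocks: list[tuple[str, int]], quotas: dict[str, int]
) -> dict[str, str]:
    """Fallback: largest-remaining-quota greedy (may miss quotas by a few)."""
    remaining = dict(quotas)
    out = {}
    for pid, s in blocks:
        part = max(PARTITIONS, key=lambda p: remaining[p])
        out[pid] = part
        remaining[part] -= s
    return out


def build_rehearsal_splits(
    priming_assignment: SplitAssignment,
    prior_sites: Sequence[SiteRecord],
    new_sites: Sequence[SiteRecord],
    seed: int = 0,
    target_fractions: Sequence[float] = DEFAULT_TARGET_FRACTIONS,
    target_counts: Optional[Sequence[int]] = None,
) -> SplitAssignment:
    """Compose the rehearsal train/validation/test assignment.

    ``target_counts`` (train, validation, test), when given, overrides the
    proportional targets — used to pin an exact published dataset shape.
    """
    bad = [s.site_id for s in new_sites if s.cohort != "low_prevalence"]
    if bad:
        raise ValueError(f"new sites must come from the low-prevalence cohort: {bad[:3]}")
    rng = np.random.default_rng(seed)
    out = SplitAssignment(
        stage="rehearsal",
        seed=seed,
        params={"target_fractions": tuple(target_fractions), "target_counts": target_counts},
    )

    # (a) prior sites keep their priming partition; contralateral normals of
    # lesion patients are dropped
    lesion_patients = {s.patient_id for s in prior_sites if s.is_referral}
    for s in prior_sites:
        if s.site_id not in priming_assignment.mapping:
            raise ValueError(f"prior site {s.site_id} missing from priming assignment")
        if s.contralateral_normal and s.patient_id in lesion_patients:
            out.notes[s.site_id] = "dropped_contralateral"
            continue
        out.mapping[s.site_id] = priming_assignment.mapping[s.site_id]
        out.notes[s.site_id] = "prior_maintained"

    # (b) all new-study referral sites to test; grouping dominates
    referred_patients = {s.patient_id for s in new_sites if s.is_referral}
    remaining: dict[str, list[SiteRecord]] = {}
    for s in new_sites:
        if s.patient_id in referred_patients:
            out.mapping[s.site_id] = "test"
            out.notes[s.site_id] = (
                "forced_test_referral" if s.is_referral else "grouped_with_referral"
            )
        else:
            remaining.setdefault(s.patient_id, []).append(s)

    # (c) allocate remaining new-study patients as whole blocks to meet the
    # overall partition targets
    n_total = len(out.mapping) + sum(len(v) for v in remaining.values())
    if target_counts is not None:
        targets = dict(zip(PARTITIONS, target_counts))
        if sum(targets.values()) != n_total:
            raise ValueError(
                f"target_counts sum to {sum(targets.values())} but {n_total} sites are available"
            )
    else:
        targets = dict(zip(PARTITIONS, _integer_targets(target_fractions, n_total)))
    current = {p: sum(1 for v in out.mapping.values() if v == p) for p in PARTITIONS}
    quotas = {p: max(targets[p] - current[p], 0) for p in PARTITIONS}
    n_remaining = sum(len(v) for v in remaining.values())
    # clip/round slack lands on the test quota (the largest partition)
    quotas["test"] += n_remaining - sum(quotas.values())
    if quotas["test"] < 0:
        quotas["train"] += quotas["test"]
        quotas["test"] = 0

    blocks = [(pid, len(remaining[pid])) for pid in sorted(remaining)]
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    assignment = _exact_block_assignment(blocks, quotas["train"], quotas["validation"], rng)
    if assignment is None:
        assignment = _greedy_block_assignment(blocks, quotas)
    for pid, part in assignment.items():
        for s in remaining[pid]:
            out.mapping[s.site_id] = part
            out.notes[s.site_id] = "grouped_random"
    return out


def audit_splits(
    assignment: SplitAssignment, sites: Sequence[SiteRecord]
) -> dict:
    """Machine-readable verification of the split rules.

    Returns ``{"checks": {rule: {"pass": bool, "detail": ...}}, "counts":
    ..., "proportions": ...}``.  ``sites`` must contain every site the
    assignment was built from (including dropped ones).
    """
    by_id = {s.site_id: s for s in sites}
    checks: dict[str, dict] = {}

    missing = [sid for sid in assignment.mapping if sid not in by_id]
    part_of = assignment.mapping

    counts = {p: 0 for p in PARTITIONS}
    class_counts = {p: {"refer": 0, "do_not_refer": 0} for p in PARTITIONS}
    for sid, p in part_of.items():
        if sid in by_id:
            counts[p] += 1
            key = "refer" if by_id[sid].is_referral else "do_not_refer"
            class_counts[p][key] += 1
    n_assigned = sum(counts.values())
    proportions = {p: counts[p] / n_assigned if n_assigned else 0.0 for p in PARTITIONS}

    checks["known_sites"] = {"pass": not missing, "detail": missing[:5]}

    # no site in two partitions is structural (dict); check conservation
    expected = {s.site_id for s in sites}
    covered = set(part_of) | set(assignment.dropped)
    checks["conservation"] = {
        "pass": covered == expected,
        "detail": {
            "unassigned": sorted(expected - covered)[:5],
            "unexpected": sorted(covered - expected)[:5],
        },
    }

    if assignment.stage == "rehearsal":
        # patient grouping within the new cohort
        patient_parts: dict[str, set[str]] = {}
        for sid, p in part_of.items():
            s = by_id.get(sid)
            if s is not None and s.cohort == "low_prevalence":
                patient_parts.setdefault(s.patient_id, set()).add(p)
        leaks = sorted(pid for pid, parts in patient_parts.items() if len(parts) > 1)
        checks["patient_disjointness"] = {"pass": not leaks, "detail": leaks[:5]}

        # every new-study referral site in test
        stray = sorted(
            sid
            for sid, p in part_of.items()
            if sid in by_id
            and by_id[sid].cohort == "low_prevalence"
            and by_id[sid].is_referral
            and p != "test"
        )
        checks["referrals_in_test"] = {"pass": not stray, "detail": stray[:5]}

        # test contains only new-study sites
        foreign = sorted(
            sid
            for sid, p in part_of.items()
            if p == "test" and sid in by_id and by_id[sid].cohort != "low_prevalence"
        )
        checks["test_only_new_cohort"] = {"pass": not foreign, "detail": foreign[:5]}

        # dropped sites really are contralateral normals of lesion patients
        lesion_patients = {s.patient_id for s in sites if s.is_referral}
        bad_drop = sorted(
            sid
            for sid in assignment.dropped
            if sid in by_id
            and not (
                by_id[sid].contralateral_normal
                and by_id[sid].patient_id in lesion_patients
            )
        )
        checks["drops_are_contralateral"] = {"pass": not bad_drop, "detail": bad_drop[:5]}

    if assignment.stage == "priming":
        ratio = assignment.params.get("ratio", 0.8)
        offenders = []
        strata: dict[str, list[str]] = {}
        for sid in part_of:
            if sid in by_id:
                strata.setdefault(by_id[sid].referral_label, []).append(sid)
        for label, ids in strata.items():
            n_train = sum(1 for sid in ids if part_of[sid] == "train")
            if len(ids) >= 2 and abs(n_train - round(ratio * len(ids))) > 1:
                offenders.append(label)
        checks["stratification"] = {"pass": not offenders, "detail": offenders}

    test_refer = class_counts["test"]["refer"]
    test_total = counts["test"]
    return {
        "stage": assignment.stage,
        "checks": checks,
        "all_pass": all(c["pass"] for c in checks.values()),
        "counts": counts,
        "class_counts": class_counts,
        "n_sites": n_assigned,
        "n_dropped": len(assignment.dropped),
        "proportions": proportions,
        "rounded_percent": {p: round(100 * proportions[p]) for p in PARTITIONS},
        "test_referral_percent": (100 * test_refer / test_total) if test_total else 0.0,
    }
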