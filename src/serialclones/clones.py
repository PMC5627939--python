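"""Partitioning variants into subclones across serial samples.

The core observation this module operationalizes: when a tumor's dominant
cell population is replaced between serial samples, the somatic variants
split into (nearly) mutually exclusive sets — one per subclone — plus a small
truncal set present throughout. Variants are first thresholded into a binary
presence matrix on the alternative allele ratio, then grouped by presence
profile; profile groups define clones, an exclusivity index quantifies how
mutually exclusive the clone sets are, and a replacement detector scans
adjacent time points for a dominance hand-over between clones.

No mixture-model deconvolution is attempted: clones are presence-profile
equivalence classes (with a one-cell noise tolerance), which is sufficient
when subclone fractions are far apart, as in a hard clonal sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import VafMatrix


def call_presence(matrix: VafMatrix, presence_vaf: float = 0.10) -> pd.DataFrame:
    """Binary presence matrix: VAF strictly greater than ``presence_vaf``.

    The threshold is strict (a cell exactly at the threshold is absent).
    Missing cells (NaN VAF) propagate as pandas NA, distinct from False.
    """
    vals = matrix.vaf.to_numpy(dtype=float)
    out = pd.DataFrame(
        pd.array(vals > presence_vaf, dtype="boolean"),
        index=matrix.vaf.index,
        columns=matrix.vaf.columns,
    )
    return out.mask(matrix.vaf.isna())


@dataclass
class ReplacementEvent:
    """A clonal hand-over between two adjacent time points."""

    clone_out: str
    clone_in: str
    sample_from: str
    sample_to: str


@dataclass
class ClonePartition:
    """Assignment of variants to clone-defining sets.

    ``assignments`` maps each variant key to a clone label ("A", "B", ...),
    "shared" (present in every sample), or "unassigned" (absent everywhere,
    or a singleton profile that matches no clone). ``clone_profiles`` holds
    each clone's defining presence profile over samples; ``presence_fraction``
    is, per clone and sample, the fraction of the clone's variants called
    present there.
    """

    samples: list[str]
    assignments: dict[str, str]
    clone_profiles: pd.DataFrame  # clones x samples, bool
    presence_fraction: pd.DataFrame  # clones x samples, float
    exclusivity_index: float
    replacement_events: list[ReplacementEvent] = field(default_factory=list)

    @property
    def clones(self) -> list[str]:
        return [c for c in self.clone_profiles.index if c != "shared"]

    def clone_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.assignments.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def write_tsv(self, path: str | Path) -> None:
        pd.Series(self.assignments, name="clone").rename_axis("variant_key").to_csv(
            path, sep="\t"
        )


def _hamming(a: tuple[bool, ...], b: tuple[bool, ...]) -> int:
    return sum(x != y for x, y in zip(a, b))


def partition_clones(
    presence: pd.DataFrame,
    min_clone_size: int = 2,
    merge_hamming: int = 1,
) -> ClonePartition:
    """Group variants by presence profile into clones, shared, and unassigned.

    Profiles present in every sample are "shared" (unless they are the only
    profile, in which case they form the sole clone). Remaining profiles of
    size >= ``min_clone_size`` become clones, labeled A, B, ... by the first
    sample in which they appear (ties: larger first). Smaller (noisy) profiles
    are absorbed into the nearest clone within ``merge_hamming`` mismatches;
    unabsorbable ones stay "unassigned". Unknown (NA) cells are treated as
    absent for grouping.
    """
    if presence.shape[1] < 2:
        raise ValueError("clone partition is undefined on a single sample")
    samples = list(presence.columns)
    filled = presence.fillna(False).astype(bool)
    profiles: dict[tuple[bool, ...], list[str]] = {}
    for key, row in zip(filled.index, filled.to_numpy()):
        profiles.setdefault(tuple(bool(x) for x in row), []).append(key)

    all_true = tuple([True] * len(samples))
    all_false = tuple([False] * len(samples))
    assignments: dict[str, str] = {}

    unassigned = profiles.pop(all_false, [])
    shared = profiles.pop(all_true, [])
    if shared and not profiles:
        # everything truncal: a single clone, shared semantics collapse
        core = {all_true: shared}
        shared = []
    else:
        core = {p: v for p, v in profiles.items() if len(v) >= min_clone_size}
        minors = {p: v for p, v in profiles.items() if len(v) < min_clone_size}
        for prof, keys in minors.items():
            candidates = [
                (d, -len(core[p]), p)
                for p in core
                if (d := _hamming(prof, p)) <= merge_hamming
            ]
            if candidates:
                core[min(candidates)[2]].extend(keys)
            else:
                unassigned.extend(keys)

    # label clones by first appearance, then size
    order = sorted(
        core, key=lambda p: (p.index(True) if True in p else len(p), -len(core[p]))
    )
    labels = [chr(ord("A") + i) for i in range(len(order))]
    for label, prof in zip(labels, order):
        for key in core[prof]:
            assignments[key] = label
    for key in shared:
        assignments[key] = "shared"
    for key in unassigned:
        assignments[key] = "unassigned"

    profile_rows = {label: list(prof) for label, prof in zip(labels, order)}
    if shared:
        profile_rows["shared"] = [True] * len(samples)
    clone_profiles = pd.DataFrame.from_dict(
        profile_rows, orient="index", columns=samples
    ).astype(bool)

    # per-clone observed presence fraction per sample
    frac_rows = {}
    for label in clone_profiles.index:
        keys = [k for k, v in assignments.items() if v == label]
        frac_rows[label] = filled.loc[keys].mean(axis=0).astype(float)
    presence_fraction = pd.DataFrame(frac_rows).T[samples]

    exclusivity = _exclusivity_index(filled, assignments, clone_profiles, labels)
    return ClonePartition(
        samples=samples,
        assignments=assignments,
        clone_profiles=clone_profiles,
        presence_fraction=presence_fraction,
        exclusivity_index=exclusivity,
    )


def _exclusivity_index(
    filled: pd.DataFrame,
    assignments: dict[str, str],
    clone_profiles: pd.DataFrame,
    clone_labels: list[str],
) -> float:
    """1 minus the fraction of clone-assigned variants that intrude into
    another clone's characteristic samples.

    A clone's characteristic samples are those where its profile is present
    and every other clone's is absent. A variant violates exclusivity when it
    is observed in a characteristic sample of a clone it does not belong to.
    """
    if not clone_labels:
        return 1.0
    char: dict[str, list[str]] = {}
    for label in clone_labels:
        others = [l for l in clone_labels if l != label]
        mask = clone_profiles.loc[label]
        for other in others:
            mask = mask & ~clone_profiles.loc[other]
        char[label] = [s for s in filled.columns if bool(mask[s])]

    assigned = [k for k, v in assignments.items() if v in clone_labels]
    if not assigned:
        return 1.0
    violations = 0
    for key in assigned:
        own = assignments[key]
        row = filled.loc[key]
        if any(
            bool(row[s]) for label in clone_labels if label != own for s in char[label]
        ):
            violations += 1
    return 1.0 - violations / len(assigned)


def detect_replacement(
    partition: ClonePartition,
    ordered_samples: Sequence[str] | None = None,
) -> list[ReplacementEvent]:
    """Scan adjacent time points for a clonal hand-over.

    An event (X out, Y in) is emitted between samples i and i+1 when clone
    X's presence fraction falls below half of its level at i and below 0.5
    absolute, while clone Y's presence fraction holds at least its level at i
    (within a small noise slack) and at least 0.5 — i.e. X loses dominance
    exactly where Y holds or gains it. With a single clone no event can occur.
    """
    samples = list(ordered_samples) if ordered_samples is not None else partition.samples
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample labels in ordering")
    if set(samples) != set(partition.samples):
        raise ValueError("ordering must be a permutation of the partition's samples")
    clones = partition.clones
    events: list[ReplacementEvent] = []
    frac = partition.presence_fraction[samples]
    for i in range(len(samples) - 1):
        s0, s1 = samples[i], samples[i + 1]
        for out_clone in clones:
            f_prev, f_next = float(frac.at[out_clone, s0]), float(frac.at[out_clone, s1])
            if not (f_next < 0.5 * f_prev and f_next < 0.5):
                continue
            for in_clone in clones:
                if in_clone == out_clone:
                    continue
                g_prev, g_next = float(frac.at[in_clone, s0]), float(frac.at[in_clone, s1])
                # small slack so a noisy one-cell dip cannot mask a hand-over
                if g_next >= g_prev - 0.1 and g_next >= 0.5:
                    events.append(ReplacementEvent(out_clone, in_clone, s0, s1))
    return events
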