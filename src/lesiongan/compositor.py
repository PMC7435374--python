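"""Composite semantic labels: patient A's tumor on patient B's brain background.

Given the semantic labels of a tumor donor A and a background donor B,
the composite label s_ab mimics the counterfactual "patient B carries
patient A's lesion": B's own tumor is relabeled to healthy tissue and
A's tumor codes are stamped at their original pixel coordinates wherever
they land inside B's brain.  From n patients this yields n^2 - n ordered
donor pairs.

Tumor pixels of A that fall outside B's brain are dropped; pairs losing
more than ``max_dropped`` of the tumor are rejected as inadmissible so a
caller can skip to another pair (a truncated lesion would make a
misleading training target).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .preprocessing import SemanticLabel

DEFAULT_MAX_DROPPED = 0.05


class InadmissiblePairError(ValueError):
    """The donor pair would truncate too much of the pasted tumor."""

    def __init__(self, dropped_fraction: float, max_dropped: float):
        self.dropped_fraction = dropped_fraction
        self.max_dropped = max_dropped
        super().__init__(
            f"{dropped_fraction:.1%} of the donor tumor falls outside the background "
            f"brain (limit {max_dropped:.1%}); pair is inadmissible")


@dataclasses.dataclass
class CompositeLabel:
    """A virtual label s_ab plus the provenance of its two donors."""

    label: SemanticLabel
    tumor_donor: tuple[str, int]
    background_donor: tuple[str, int]
    dropped_fraction: float


def composite_label(s_a: SemanticLabel, s_b: SemanticLabel,
                    max_dropped: float = DEFAULT_MAX_DROPPED) -> CompositeLabel:
    """Build s_ab from tumor donor ``s_a`` and background donor ``s_b``."""
    if s_a.classes.shape != s_b.classes.shape:
        raise ValueError("semantic labels differ in shape")
    tumor_a = s_a.tumor_mask()
    n_tumor = int(tumor_a.sum())
    if n_tumor == 0:
        raise ValueError("tumor donor label contains no tumor pixels")

    out = s_b.classes.copy()
    out[s_b.tumor_mask()] = 1  # B's own lesion reverts to healthy tissue
    brain_b = s_b.brain_mask()
    paste = tumor_a & brain_b
    out[paste] = s_a.classes[paste]

    dropped = n_tumor - int(paste.sum())
    dropped_fraction = dropped / n_tumor
    if dropped_fraction > max_dropped:
        raise InadmissiblePairError(dropped_fraction, max_dropped)

    label = SemanticLabel(classes=out,
                          patient_id=f"{s_a.patient_id}->{s_b.patient_id}",
                          slice_index=s_b.slice_index)
    return CompositeLabel(
        label=label,
        tumor_donor=(s_a.patient_id, s_a.slice_index),
        background_donor=(s_b.patient_id, s_b.slice_index),
        dropped_fraction=dropped_fraction,
    )


def enumerate_pairs(patient_ids: list[str]) -> list[tuple[str, str]]:
    """All ordered donor pairs (tumor donor, background donor), a != b.

    For n unique patients this is exactly n*(n-1) pairs — e.g. 226 patients
    give 50,850 virtual samples.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient id(s): {dupes}")
    return [(a, b) for a, b in itertools.product(sorted(ids), repeat=2) if a != b]


def sample_pairs(pairs: list[tuple[str, str]], k: int, seed: int) -> list[tuple[str, str]]:
    """Uniform sample of ``k`` pairs without replacement, deterministic per seed."""
    if k < 0 or k > len(pairs):
        raise ValueError(f"cannot sample {k} of {len(pairs)} pairs")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pairs))[:k]
    return [pairs[i] for i in idx]
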