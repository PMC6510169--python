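"""The 188-dimensional composition/transition/distribution (CTD) descriptor.

The descriptor concatenates the 20 amino-acid composition percentages with,
for each of eight physicochemical properties, a 21-value CTD block:

* composition — the percentage of residues falling in each of the property's
  three groups (3 values);
* transition — for each unordered group pair, the percentage of adjacent
  residue pairs whose members lie in the two different groups, out of the
  L - 1 adjacent pairs (3 values);
* distribution — for each group, the sequence positions (1-based, as a
  percentage of L) of the first, 25%, 50%, 75% and last occurrences of the
  group's residues (15 values).

Total: 20 + 8 x (3 + 3 + 15) = 188.

Each property partitions the 20 standard residues into three groups
(e.g. hydrophobicity: polar / neutral / hydrophobic).  The partitions are
the classical three-group CTD assignments and ship as a packaged data table
(``data/ctd_groups.tsv``) so they can be inspected and, if needed, edited.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import ConfigurationError
from .seqio import ALPHABET, ProteinSequence, validate_sequence

#: Quantile labels of the five distribution descriptors per group.
DISTRIBUTION_POINTS = ("first", "p25", "p50", "p75", "p100")


@dataclass(frozen=True)
class PropertyGrouping:
    """A named exact 3-way partition of the 20 standard residues."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.groups)
        if sorted(joined) != sorted(ALPHABET):
            raise ConfigurationError(
                f"groups of property {self.name!r} must partition the 20-letter alphabet"
            )

    def group_of(self, residue: str) -> int:
        """Return the 0-based group index of a residue."""
        for g, members in enumerate(self.groups):
            if residue in members:
                return g
        raise KeyError(residue)

    def membership(self) -> dict[str, int]:
        return {res: g for g, members in enumerate(self.groups) for res in members}


@lru_cache(maxsize=1)
def load_groupings() -> tuple[PropertyGrouping, ...]:
    """Load the eight packaged property groupings, in canonical order."""
    ref = resources.files("chanpred").joinpath("data/ctd_groups.tsv")
    with ref.open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        groupings = tuple(
            PropertyGrouping(row["property"], (row["group1"], row["group2"], row["group3"]))
            for row in reader
        )
    if len(groupings) != 8:
        raise ConfigurationError(f"expected 8 property groupings, found {len(groupings)}")
    return groupings


def aa_composition(seq: ProteinSequence) -> np.ndarray:
    """Amino-acid composition: per-residue percentage count/L x 100.

    Residue order is fixed alphabetical (ACDEFGHIKLMNPQRSTVWY).
    """
    counts = np.array([seq.residues.count(res) for res in ALPHABET], dtype=float)
    return counts / seq.length * 100.0


def group_composition(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    """Percentage of residues in each of the grouping's three groups."""
    member = grouping.membership()
    counts = np.zeros(3)
    for res in seq.residues:
        counts[member[res]] += 1
    return counts / seq.length * 100.0


def group_transition(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    """Adjacent inter-group transition percentages, pairs (1,2), (1,3), (2,3).

    A transition at position t is an adjacent pair (t, t+1) whose residues
    fall in two different groups; either order counts.  The denominator is
    L - 1.  A length-1 sequence has no adjacent pairs and yields zeros.
    """
    if seq.length < 2:
        return np.zeros(3)
    member = grouping.membership()
    groups = [member[res] for res in seq.residues]
    counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
    for a, b in zip(groups, groups[1:]):
        if a != b:
            counts[(min(a, b), max(a, b))] += 1
    total = seq.length - 1
    return np.array([counts[(0, 1)], counts[(0, 2)], counts[(1, 2)]]) / total * 100.0


def group_distribution(seq: ProteinSequence, grouping: PropertyGrouping) -> np.ndarray:
    """Scaled positions of the first/25%/50%/75%/100% occurrences per group.

    For a group with m occurrences, the five descriptors are the 1-based
    sequence positions of its 1st, ceil(0.25 m)-th, ceil(0.50 m)-th,
    ceil(0.75 m)-th and m-th occurrences, each divided by L and scaled to a
    percentage.  An absent group (m = 0) yields five zeros.
    """
    member = grouping.membership()
    positions: list[list[int]] = [[], [], []]
    for pos, res in enumerate(seq.residues, start=1):
        positions[member[res]].append(pos)
    out = np.zeros(15)
    for g in range(3):
        occ = positions[g]
        m = len(occ)
        if m == 0:
            continue
        idxs = [1, math.ceil(0.25 * m), math.ceil(0.50 * m), math.ceil(0.75 * m), m]
        for j, idx in enumerate(idxs):
            out[5 * g + j] = occ[max(idx, 1) - 1] / seq.length * 100.0
    return out


@lru_cache(maxsize=1)
def feature_names_188() -> tuple[str, ...]:
    """The fixed 188-entry feature-name index of :func:`extract_188`."""
    names = [f"AAC.{res}" for res in ALPHABET]
    for grouping in load_groupings():
        p = grouping.name
        names += [f"{p}.C{g}" for g in (1, 2, 3)]
        names += [f"{p}.T12", f"{p}.T13", f"{p}.T23"]
        for g in (1, 2, 3):
            names += [f"{p}.D{g}.{point}" for point in DISTRIBUTION_POINTS]
    return tuple(names)


def extract_188(seq: ProteinSequence, min_length: int | None = None) -> np.ndarray:
    """Compute the full 188-D descriptor for one sequence.

    Concatenation order: amino-acid composition (20), then for each property
    in the packaged order: composition (3), transition (3), distribution (15).
    Raises ``ValueError`` with the verdict reason for invalid sequences.
    """
    kwargs = {} if min_length is None else {"min_length": min_length}
    verdict = validate_sequence(seq.residues, **kwargs)
    if not verdict:
        raise ValueError(f"invalid sequence {seq.id!r}: {verdict.reason}")
    blocks = [aa_composition(seq)]
    for grouping in load_groupings():
        blocks.append(group_composition(seq, grouping))
        blocks.append(group_transition(seq, grouping))
        blocks.append(group_distribution(seq, grouping))
    vec = np.concatenate(blocks)
    assert vec.shape == (188,)
    return vec
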