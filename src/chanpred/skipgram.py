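"""The 400-dimensional k-skip-n-gram descriptor for n = 2.

A skip-gram pair with gap ``a`` joins the residues at positions i and
i + a + 1 (so the positional distance DT between them, the number of
residues strictly between, equals ``a``).  The descriptor pools the pairs
for all gaps a = 1..k (optionally also a = 0, i.e. contiguous dipeptides)
into one multiset T and reports, for each of the 400 ordered residue pairs,
its count in T divided by |T|.  Pairs are directional: (A, C) and (C, A)
are distinct entries; 20^2 = 400.

The gap limit k is a free parameter of the method with no canonical value;
it defaults to 2 here and is always recorded in run configs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ConfigurationError
from .seqio import ALPHABET, ProteinSequence, validate_sequence

DEFAULT_K = 2


@dataclass(frozen=True)
class SkipGramConfig:
    """Configuration of the skip-gram encoder.

    ``k`` is the maximum gap between the two residues of a pair; ``n`` is
    the gram length (only 2 is supported — 20^n features explode for
    n >= 3); ``include_zero_gap`` additionally pools contiguous dipeptides
    (gap 0) into the term multiset.
    """

    k: int = DEFAULT_K
    n: int = 2
    include_zero_gap: bool = False

    def __post_init__(self) -> None:
        if self.n != 2:
            raise ConfigurationError(
                f"only n=2 (400 ordered residue pairs) is supported, got n={self.n}"
            )
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")

    @property
    def gaps(self) -> range:
        return range(0 if self.include_zero_gap else 1, self.k + 1)


def skip_pairs(seq: ProteinSequence, a: int) -> Counter[str]:
    """All ordered residue pairs at gap ``a``, as a multiset.

    Pairs join positions (i, i + a + 1) for every i with both positions
    inside the sequence; a sequence with L <= a + 1 yields the empty
    multiset.
    """
    if a < 0:
        raise ConfigurationError(f"gap must be >= 0, got {a}")
    r = seq.residues
    step = a + 1
    return Counter(r[i] + r[i + step] for i in range(len(r) - step))


@lru_cache(maxsize=1)
def feature_names_400() -> tuple[str, ...]:
    """Ordered pair names AA, AC, ..., YY in row-major alphabetical order."""
    return tuple(f"SKIP.{x}{y}" for x in ALPHABET for y in ALPHABET)


def extract_kskip(seq: ProteinSequence, config: SkipGramConfig = SkipGramConfig()) -> np.ndarray:
    """Compute the 400-D skip-gram frequency vector for one sequence.

    Entry order matches :func:`feature_names_400`.  When the pooled term
    multiset is empty (sequence too short for every gap) the vector is all
    zeros; otherwise it sums to 1.
    """
    verdict = validate_sequence(seq.residues)
    if not verdict:
        raise ValueError(f"invalid sequence {seq.id!r}: {verdict.reason}")
    pooled: Counter[str] = Counter()
    for a in config.gaps:
        pooled.update(skip_pairs(seq, a))
    vec = np.zeros(400)
    total = sum(pooled.values())
    if total == 0:
        return vec
    index = {x + y: i for i, (x, y) in enumerate((x, y) for x in ALPHABET for y in ALPHABET)}
    for pair, count in pooled.items():
        vec[index[pair]] = count / total
    return vec
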