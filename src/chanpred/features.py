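"""Feature-matrix plumbing shared by the encoders, selector and classifiers.

A feature matrix is a pandas DataFrame: rows indexed by sequence id, columns
named features, written/read as TSV with the index in the first column
(header ``id``).  The same dialect is produced by the encoders and consumed
by MRMD selection and the classifiers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ctd import extract_188, feature_names_188
from .errors import ConfigurationError
from .seqio import ProteinSequence
from .skipgram import SkipGramConfig, extract_kskip, feature_names_400

ENCODERS = ("ctd188", "skipgram400", "fused588")

#: Fixed float format for matrix files so identical runs are byte-identical.
FLOAT_FORMAT = "%.10g"


def encode_sequence(
    seq: ProteinSequence,
    encoder: str = "ctd188",
    skip_config: SkipGramConfig = SkipGramConfig(),
) -> np.ndarray:
    if encoder == "ctd188":
        return extract_188(seq)
    if encoder == "skipgram400":
        return extract_kskip(seq, skip_config)
    if encoder == "fused588":
        return np.concatenate([extract_188(seq), extract_kskip(seq, skip_config)])
    raise ConfigurationError(f"unknown encoder {encoder!r}; known: {ENCODERS}")


def encoder_feature_names(encoder: str = "ctd188") -> tuple[str, ...]:
    if encoder == "ctd188":
        return feature_names_188()
    if encoder == "skipgram400":
        return feature_names_400()
    if encoder == "fused588":
        return feature_names_188() + feature_names_400()
    raise ConfigurationError(f"unknown encoder {encoder!r}; known: {ENCODERS}")


def encode_dataset(
    sequences: Iterable[ProteinSequence],
    encoder: str = "ctd188",
    skip_config: SkipGramConfig = SkipGramConfig(),
) -> pd.DataFrame:
    """Encode sequences into a feature matrix (rows in input order)."""
    names = encoder_feature_names(encoder)
    rows = {}
    for seq in sequences:
        rows[seq.id] = encode_sequence(seq, encoder, skip_config)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    matrix.index.name = "id"
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix = matrix.copy()
    matrix.index.name = "id"
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
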