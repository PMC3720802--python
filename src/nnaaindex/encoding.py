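"""Peptide sequence parsing and positional descriptor encoding.

Sequences mix natural one-letter residue codes with numeric identifiers for
non-natural residues.  Two dialects are accepted: compact ("TLTRV108W", where
a maximal digit run is one residue token) and hyphen-separated ("512-439").
A peptide of length L encoded against an m-factor scale table yields an
m*L-dimensional descriptor vector, position-major, with variables named
``pos{i}.{factor_name}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import ScaleTable

__all__ = [
    "Peptide",
    "DescriptorMatrix",
    "parse_sequence",
    "format_sequence",
    "encode_peptide",
    "encode_dataset",
]


@dataclass
class Peptide:
    tokens: list[str]
    activity: float | str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("peptide must have at least one residue token")
        self.tokens = [str(t) for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def sequence(self) -> str:
        return format_sequence(self.tokens)


@dataclass
class DescriptorMatrix:
    sample_ids: list[str]
    variable_names: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.variable_names)


def parse_sequence(text: str) -> Peptide:
    """Parse a peptide token string, N-terminus first.

    Letters are single-residue tokens; maximal digit runs are single numeric
    tokens; hyphens separate tokens explicitly.  Natural codes are
    case-insensitive and normalized to uppercase.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty sequence string")
    s = text.strip()
    tokens: list[str] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "-":
            if i == 0 or i == len(s) - 1 or s[i - 1] == "-":
                raise ValueError(f"misplaced '-' at position {i} in {text!r}")
            i += 1
        elif ch.isdigit():
            j = i
            while j < len(s) and s[j].isdigit():
                j += 1
            tokens.append(s[i:j])
            i = j
        elif ch.isalpha():
            tokens.append(ch.upper())
            i += 1
        else:
            raise ValueError(
                f"invalid character {ch!r} at position {i} in sequence {text!r}"
            )
    if not tokens:
        raise ValueError(f"no residue tokens in {text!r}")
    return Peptide(tokens=tokens)


def format_sequence(tokens: list[str]) -> str:
    """Canonical sequence string: hyphen-separated when any token is numeric,
    compact concatenation otherwise."""
    tokens = [str(t) for t in tokens]
    if any(t.isdigit() for t in tokens):
        return "-".join(tokens)
    return "".join(tokens)


def descriptor_names(length: int, factor_names: list[str]) -> list[str]:
    return [f"pos{i + 1}.{f}" for i in range(length) for f in factor_names]


def encode_peptide(p: Peptide, scales: ScaleTable) -> np.ndarray:
    """Positional concatenation of factor scores: pos1.f1..pos1.fm, pos2.f1.."""
    vecs = []
    for pos, tok in enumerate(p.tokens, start=1):
        if tok not in scales:
            raise KeyError(
                f"unknown residue {tok!r} at position {pos}"
                + (f" of sample {p.sample_id!r}" if p.sample_id else "")
            )
        vecs.append(scales.scores(tok))
    return np.concatenate(vecs)


def encode_dataset(peptides: list[Peptide], scales: ScaleTable) -> DescriptorMatrix:
    """Encode equal-length peptides into an n x (m*L) descriptor matrix."""
    if not peptides:
        raise ValueError("empty peptide list")
    L = len(peptides[0])
    bad = [p.sample_id or f"#{k}" for k, p in enumerate(peptides) if len(p) != L]
    if bad:
        raise ValueError(f"peptides of differing length (expected {L}): {bad}")
    rows = np.vstack([encode_peptide(p, scales) for p in peptides])
    ids = [p.sample_id or f"#{k}" for k, p in enumerate(peptides)]
    return DescriptorMatrix(
        sample_ids=ids,
        variable_names=descriptor_names(L, scales.factor_names),
        values=rows,
    )
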