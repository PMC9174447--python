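"""Tokenization of molecule strings and integer coding for the language model.

SMILES are segmented greedily left-to-right keeping chemically atomic units
intact: bracket atoms ``[...]``, two-digit ring closures ``%dd`` and the
two-letter halogens ``Cl``/``Br`` are single tokens; every other character is
its own token. Robust bracket strings tokenize one bracketed group per token.
Concatenating the tokens always reproduces the source string exactly.

Special tokens occupy fixed indices (PAD=0, BOS=1, EOS=2) so that checkpoints
are reproducible across runs; the remaining vocabulary is sorted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"
SPECIALS = (PAD, BOS, EOS)

_SMILES_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|%\d\d|Cl|Br|.")
_BRACKET_RE = re.compile(r"\[[^\[\]]*\]")


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    """An ordered list of string tokens; joining them reproduces the source."""

    tokens: tuple[str, ...]

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def tokenize_smiles(s: str) -> TokenSequence:
    """Greedy segmentation of a SMILES string into chemically atomic tokens."""
    if not s:
        raise TokenizationError("cannot tokenize an empty SMILES string")
    tokens: list[str] = []
    pos = 0
    for m in _SMILES_TOKEN_RE.finditer(s):
        tok = m.group(0)
        if tok == "[":
            raise TokenizationError(f"unclosed '[' at position {m.start()} in {s!r}")
        if tok == "]":
            raise TokenizationError(f"stray ']' at position {m.start()} in {s!r}")
        tokens.append(tok)
        pos = m.end()
    assert pos == len(s)
    return TokenSequence(tuple(tokens))


def tokenize_selfies(s: str) -> TokenSequence:
    """One token per bracketed group; empty input gives an empty sequence."""
    tokens: list[str] = []
    pos = 0
    for m in _BRACKET_RE.finditer(s):
        if m.start() != pos:
            raise TokenizationError(
                f"stray characters at position {pos} in {s!r}: {s[pos:m.start()]!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(s):
        raise TokenizationError(
            f"stray characters at position {pos} in {s!r}: {s[pos:]!r}"
        )
    return TokenSequence(tuple(tokens))


def tokenize(s: str, encoding: str) -> TokenSequence:
    if encoding == "smiles":
        return tokenize_smiles(s)
    if encoding == "selfies":
        return tokenize_selfies(s)
    raise ValueError(f"unknown encoding {encoding!r}")


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective token<->index map with PAD/BOS/EOS reserved at indices 0-2."""

    tokens: tuple[str, ...]
    token_to_index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if tuple(self.tokens[:3]) != SPECIALS:
            raise ValueError("vocabulary must start with PAD, BOS, EOS")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(
            self, "token_to_index", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def bos_index(self) -> int:
        return 1

    @property
    def eos_index(self) -> int:
        return 2

    def index(self, token: str) -> int:
        try:
            return self.token_to_index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def save(self, path: str | Path) -> None:
        """Plain-text token list, one per line, index = line number."""
        Path(path).write_text("\n".join(self.tokens) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(tuple(lines))


def build_vocabulary(corpus: Iterable[TokenSequence]) -> TokenVocabulary:
    """Specials plus all distinct corpus tokens, sorted for reproducibility."""
    seen: set[str] = set()
    n = 0
    for seq in corpus:
        n += 1
        seen.update(seq.tokens)
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if seen & set(SPECIALS):
        raise ValueError("corpus contains reserved special tokens")
    return TokenVocabulary(SPECIALS + tuple(sorted(seen)))


def encode(seq: TokenSequence, vocab: TokenVocabulary) -> list[int]:
    """Integer codes with BOS prepended and EOS appended."""
    return (
        [vocab.bos_index]
        + [vocab.index(t) for t in seq.tokens]
        + [vocab.eos_index]
    )


def decode(codes: Sequence[int], vocab: TokenVocabulary) -> str:
    """Concatenate tokens, stopping at the first EOS and skipping specials."""
    out: list[str] = []
    for c in codes:
        if not 0 <= c < len(vocab):
            raise ValueError(f"code {c} out of range for vocabulary of {len(vocab)}")
        if c == vocab.eos_index:
            break
        if c in (vocab.pad_index, vocab.bos_index):
            continue
        out.append(vocab.tokens[c])
    return "".join(out)
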