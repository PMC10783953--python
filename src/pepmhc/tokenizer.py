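"""Fixed-width word tokenization of amino-acid sequences.

Sequences are prepended with a pad character until their length is divisible
by the word size, then split into non-overlapping words.  Each word is further
decomposed into the multiset of all its contiguous substrings ("sub-words"),
enumerated positionally, so a word of size ``w`` always yields
``w*(w+1)/2`` sub-words (6 at the default word size of 3).  Word-level
embeddings downstream are sums over this multiset, which lets rare or unseen
words be represented through their more common parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP_CHAR = "-"
DEFAULT_PAD = "^"


@dataclass(frozen=True)
class TokenizerConfig:
    """Parameters of the word tokenizer.

    Parameters
    ----------
    word_size:
        Number of residues per non-overlapping word.  Default 3.
    pad_char:
        Character prepended to make the sequence length divisible by
        ``word_size``.  Must not be a member of ``alphabet``.
    alphabet:
        Allowed residue characters.  The 20 standard amino acids by default;
        pass ``allow_gap=True`` via :func:`aligned_config` to admit the
        alignment gap character ``-`` as an ordinary symbol (used for
        multiple-sequence-aligned allele input).
    """

    word_size: int = 3
    pad_char: str = DEFAULT_PAD
    alphabet: frozenset[str] = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if len(self.pad_char) != 1:
            raise ValueError("pad_char must be a single character")
        if self.pad_char in self.alphabet:
            raise ValueError("pad_char must not be in the alphabet")


def aligned_config(word_size: int = 3, pad_char: str = DEFAULT_PAD) -> TokenizerConfig:
    """Tokenizer configuration admitting the alignment gap character '-'."""
    return TokenizerConfig(
        word_size=word_size,
        pad_char=pad_char,
        alphabet=frozenset(AMINO_ACIDS | {GAP_CHAR}),
    )


@dataclass(frozen=True)
class TokenizedSequence:
    """A sequence split into padded fixed-width words."""

    source: str
    words: tuple[str, ...]
    pad_count: int
    config: TokenizerConfig = field(default_factory=TokenizerConfig, compare=False)

    def __len__(self) -> int:
        return len(self.words)


def _validate(seq: str, cfg: TokenizerConfig) -> str:
    if not seq:
        raise ValueError("empty input")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in cfg.alphabet:
            raise ValueError(
                f"character {ch!r} at position {i} is not in the allowed alphabet"
            )
    return seq


def pad_sequence(seq: str, cfg: TokenizerConfig = TokenizerConfig()) -> str:
    """Prepend pad characters so the length is divisible by the word size.

    Padding is prepended only: ``"ABCD"`` at word size 3 becomes ``"^^ABCD"``.
    """
    seq = _validate(seq, cfg)
    remainder = len(seq) % cfg.word_size
    n_pad = 0 if remainder == 0 else cfg.word_size - remainder
    return cfg.pad_char * n_pad + seq


def split_into_words(padded: str, cfg: TokenizerConfig = TokenizerConfig()) -> list[str]:
    """Split a padded sequence into contiguous non-overlapping words."""
    if len(padded) % cfg.word_size != 0:
        raise ValueError(
            f"length {len(padded)} is not divisible by word_size {cfg.word_size}; "
            "pad the sequence first"
        )
    w = cfg.word_size
    return [padded[i : i + w] for i in range(0, len(padded), w)]


def enumerate_subwords(word: str) -> list[str]:
    """All contiguous substrings of a word, enumerated by position.

    This is a multiset: a word with repeated substrings (e.g. ``"AAA"``)
    lists each occurrence once per (start, end) position, so every word of
    size ``w`` yields exactly ``w*(w+1)/2`` sub-words.  Ordered by length,
    then start position, matching the convention B, C, D, BC, CD, BCD.
    """
    w = len(word)
    return [
        word[start : start + length]
        for length in range(1, w + 1)
        for start in range(w - length + 1)
    ]


def tokenize(seq: str, cfg: TokenizerConfig = TokenizerConfig()) -> TokenizedSequence:
    """Pad and split a sequence, recording how many pad characters were added."""
    padded = pad_sequence(seq, cfg)
    words = split_into_words(padded, cfg)
    pad_count = len(padded) - len(_validate(seq, cfg))
    return TokenizedSequence(
        source=seq.upper(), words=tuple(words), pad_count=pad_count, config=cfg
    )
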