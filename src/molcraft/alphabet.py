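"""Chemical token alphabets for SMILES and SELFIES strings.

The decoder emits molecules token by token, so the token inventory matters:
bracket atoms (``[nH]``, ``[O-]`` ...) and a configurable list of multi-character
functional-group strings are single tokens, two-letter halogens (Cl, Br) and
``%nn`` ring closures are kept intact, and three special markers delimit the
start, end and padding of every sequence ("x"/"y"/"z" for SMILES,
``[\\X]``/``[\\Y]``/``[\\Z]`` for SELFIES).

Tokenization is greedy longest-match, and ``detokenize(tokenize(s)) == s``
holds for every representable string (specials stripped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .chem import randomized_smiles

__all__ = ["TokenAlphabet", "TokenizationError", "build_alphabet", "tokenize", "detokenize"]

SMILES_SPECIALS = ("x", "y", "z")  # start, end, pad markers
SELFIES_SPECIALS = ("[\\X]", "[\\Y]", "[\\Z]")

#: Frequent functional groups encoded as single tokens in SMILES mode
#: (sulfoxide, nitro, ketone/carbonyl, nitrile); configurable per alphabet.
DEFAULT_MULTI_CHAR_TOKENS = ("S(=O)", "[N+](=O)[O-]", "C(=O)", "C#N")

_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_RING_RE = re.compile(r"%\d{2}")


class TokenizationError(ValueError):
    def __init__(self, string: str, position: int):
        self.string = string
        self.position = position
        super().__init__(
            f"no token matches {string!r} at position {position}: {string[position:position + 8]!r}"
        )


@dataclass(frozen=True)
class TokenAlphabet:
    """Ordered token inventory Omega plus special markers.

    Index layout: 0=start, 1=end, 2=pad, then the content tokens in their
    stored (sorted, deterministic) order.
    """

    tokens: tuple[str, ...]
    specials: tuple[str, str, str]
    representation: str = "smiles"  # or "selfies"
    multi_char_tokens: tuple[str, ...] = field(default=DEFAULT_MULTI_CHAR_TOKENS)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in alphabet")
        if set(self.specials) & set(self.tokens):
            raise ValueError("special markers must not appear among content tokens")

    @property
    def start_idx(self) -> int:
        return 0

    @property
    def end_idx(self) -> int:
        return 1

    @property
    def pad_idx(self) -> int:
        return 2

    @property
    def size(self) -> int:
        return len(self.tokens) + 3

    def index_of(self, token: str) -> int:
        try:
            return self._lookup[token]
        except AttributeError:
            lookup = {t: i + 3 for i, t in enumerate(self.tokens)}
            for i, s in enumerate(self.specials):
                lookup[s] = i
            object.__setattr__(self, "_lookup", lookup)
            return self._lookup[token]

    def token_at(self, idx: int) -> str:
        if idx < 3:
            return self.specials[idx]
        return self.tokens[idx - 3]

    def to_dict(self) -> dict:
        return {
            "tokens": list(self.tokens),
            "specials": list(self.specials),
            "representation": self.representation,
            "multi_char_tokens": list(self.multi_char_tokens),
        }

    @staticmethod
    def from_dict(d: dict) -> "TokenAlphabet":
        return TokenAlphabet(
            tokens=tuple(d["tokens"]),
            specials=tuple(d["specials"]),
            representation=d.get("representation", "smiles"),
            multi_char_tokens=tuple(d.get("multi_char_tokens", DEFAULT_MULTI_CHAR_TOKENS)),
        )


def _split_tokens(s: str, representation: str, multi_char_tokens: tuple[str, ...]) -> list[str]:
    """Greedy longest-match segmentation into candidate tokens (no vocabulary check)."""
    if representation == "selfies":
        out, i = [], 0
        while i < len(s):
            m = _BRACKET_RE.match(s, i)
            if not m:
                raise TokenizationError(s, i)
            out.append(m.group())
            i = m.end()
        return out

    # SMILES: multi-char functional groups > bracket atoms > %nn > Cl/Br > single char
    multis = sorted(multi_char_tokens, key=len, reverse=True)
    out, i = [], 0
    while i < len(s):
        matched = None
        for tok in multis:
            if s.startswith(tok, i):
                matched = tok
                break
        if matched is None and s[i] == "[":
            m = _BRACKET_RE.match(s, i)
            if not m:
                raise TokenizationError(s, i)
            matched = m.group()
        if matched is None and s[i] == "%":
            m = _RING_RE.match(s, i)
            if not m:
                raise TokenizationError(s, i)
            matched = m.group()
        if matched is None and s[i : i + 2] in ("Cl", "Br"):
            matched = s[i : i + 2]
        if matched is None:
            matched = s[i]
        out.append(matched)
        i += len(matched)
    return out


def build_alphabet(
    corpus: list[str],
    n_randomizations: int = 10,
    representation: str = "smiles",
    multi_char_tokens: tuple[str, ...] = DEFAULT_MULTI_CHAR_TOKENS,
    seed: int = 0,
) -> TokenAlphabet:
    """Token alphabet covering every rendering of the corpus plus specials.

    For SMILES, each molecule contributes its canonical form and
    `n_randomizations` randomized renderings, so tokens that only appear in
    non-canonical atom orderings are still covered.  Deterministic under a
    fixed seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    representation = representation.lower()
    specials = SMILES_SPECIALS if representation == "smiles" else SELFIES_SPECIALS
    tokens: set[str] = set()
    for s in corpus:
        renderings = [s]
        if representation == "smiles":
            renderings += randomized_smiles(s, n_randomizations, seed=seed)
        for r in renderings:
            tokens.update(_split_tokens(r, representation, multi_char_tokens))
    return TokenAlphabet(
        tokens=tuple(sorted(tokens)),
        specials=specials,
        representation=representation,
        multi_char_tokens=tuple(multi_char_tokens),
    )


def tokenize(s: str, alphabet: TokenAlphabet) -> list[int]:
    """Index sequence [start, *content, end]; raises TokenizationError on gaps."""
    parts = _split_tokens(s, alphabet.representation, alphabet.multi_char_tokens)
    idx = [alphabet.start_idx]
    pos = 0
    for tok in parts:
        try:
            idx.append(alphabet.index_of(tok))
        except KeyError:
            raise TokenizationError(s, pos) from None
        pos += len(tok)
    idx.append(alphabet.end_idx)
    return idx


def detokenize(indices, alphabet: TokenAlphabet) -> str:
    """Inverse of :func:`tokenize`; start/end/pad markers are stripped."""
    return "".join(
        alphabet.token_at(int(i)) for i in indices if int(i) >= 3
    )
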