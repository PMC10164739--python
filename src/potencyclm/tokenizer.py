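"""SMILES and potency-difference tokenization.

SMILES strings are tokenized character by character, except that "Cl" and
"Br" are single tokens and any bracket atom ("[nH]", "[O-]", ...) is one
token. Potency differences (ΔpKi) are discretized into constant-width bins of
0.01 pKi units spanning −6.62 to 6.52 — 1314 bins, a resolution at the limit
of experimental potency measurement — each encoded by one token. Together
with the start/end markers (and a padding token for batching) these form the
model vocabulary.

A model input frames the source compound's SMILES tokens followed by the
potency-difference token between start/end markers; the target compound's
SMILES tokens form the output sequence.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

START = "<start>"
END = "<end>"
PAD = "<pad>"

BIN_LO = -6.62
BIN_HI = 6.52
BIN_WIDTH = 0.01

_TOKEN_RE = re.compile(r"Cl|Br|\[[^\]]*\]|.")

#: Characters the default vocabulary covers; built from the organic subset,
#: ring-closure digits, bonds and branching as RDKit canonical SMILES emit them.
DEFAULT_SMILES_CHARS = list("BCNOPSFIcnospb123456789%()=#-+/\\@.") + ["Cl", "Br"]


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; concatenating them reproduces the
    input exactly. Raises on an unclosed bracket, naming its position."""
    pos = smiles.find("[")
    while pos != -1:
        close = smiles.find("]", pos)
        if close == -1:
            raise ValueError(f"unclosed '[' at position {pos} in {smiles!r}")
        pos = smiles.find("[", close)
    return _TOKEN_RE.findall(smiles)


def n_bins(lo: float = BIN_LO, hi: float = BIN_HI, width: float = BIN_WIDTH) -> int:
    return int(round((hi - lo) / width))


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token ↔ index mapping over SMILES tokens, potency-bin tokens
    and the special markers."""

    smiles_tokens: tuple[str, ...]
    bin_lo: float = BIN_LO
    bin_hi: float = BIN_HI
    bin_width: float = BIN_WIDTH
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        pot = [self.bin_token(i) for i in range(self.n_potency_bins)]
        tokens = [PAD, START, END, *self.smiles_tokens, *pot]
        if len(set(tokens)) != len(tokens):
            raise ValueError("vocabulary tokens are not disjoint")
        object.__setattr__(self, "tokens", tuple(tokens))
        self._index.update({t: i for i, t in enumerate(tokens)})

    @property
    def n_potency_bins(self) -> int:
        return n_bins(self.bin_lo, self.bin_hi, self.bin_width)

    def __len__(self) -> int:
        return len(self.tokens)

    def bin_token(self, idx: int) -> str:
        return f"<d{idx}>"

    def index(self, token: str) -> int:
        return self._index[token]

    def encode(self, tokens: list[str]) -> list[int]:
        try:
            return [self._index[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, indices) -> list[str]:
        return [self.tokens[int(i)] for i in indices]

    def is_potency_token(self, token: str) -> bool:
        return token.startswith("<d") and token.endswith(">") and token not in (START, END, PAD)

    # -- potency binning ----------------------------------------------------

    def bin_index(self, delta: float, clamp: bool = False) -> int:
        """Half-open bins [lo + k·w, lo + (k+1)·w); the top edge closes the
        last bin. Out-of-range deltas clamp to an edge bin when ``clamp``
        (inference convenience), else raise."""
        if math.isnan(delta):
            raise ValueError("potency difference is NaN")
        if delta < self.bin_lo or delta > self.bin_hi:
            if not clamp:
                raise ValueError(
                    f"delta {delta} outside binnable range "
                    f"[{self.bin_lo}, {self.bin_hi}]")
            log.warning("clamping out-of-range delta %.3f to bin edge", delta)
            delta = min(max(delta, self.bin_lo), self.bin_hi)
        # snap to 1e-6 so exact bin edges land in the upper bin despite
        # floating-point representation error
        idx = int(math.floor(round((delta - self.bin_lo) / self.bin_width, 6)))
        return min(idx, self.n_potency_bins - 1)

    def bin_delta(self, delta: float, clamp: bool = False) -> str:
        return self.bin_token(self.bin_index(delta, clamp=clamp))

    # -- framing ------------------------------------------------------------

    def frame_source(self, smiles: str, delta: float, clamp: bool = False) -> list[str]:
        """START + source SMILES tokens + potency token + END."""
        return [START, *tokenize_smiles(smiles), self.bin_delta(delta, clamp=clamp), END]

    def frame_target(self, smiles: str) -> list[str]:
        return [START, *tokenize_smiles(smiles), END]

    def detokenize(self, tokens: list[str]) -> str:
        """Concatenate SMILES tokens, dropping specials; inverse of
        :func:`tokenize_smiles`. Raises if a potency token is embedded."""
        parts = []
        for t in tokens:
            if t in (START, END, PAD):
                continue
            if self.is_potency_token(t):
                raise ValueError(f"potency token {t!r} in a target sequence")
            parts.append(t)
        return "".join(parts)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "smiles_tokens": list(self.smiles_tokens),
            "bin_lo": self.bin_lo,
            "bin_hi": self.bin_hi,
            "bin_width": self.bin_width,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            smiles_tokens=tuple(payload["smiles_tokens"]),
            bin_lo=payload["bin_lo"],
            bin_hi=payload["bin_hi"],
            bin_width=payload["bin_width"],
        )

    @classmethod
    def build(cls, smiles_iterable, **bin_kwargs) -> "Vocabulary":
        """Vocabulary whose SMILES tokens are the default character set plus
        any token observed in ``smiles_iterable`` (bracket atoms etc.)."""
        tokens = set(DEFAULT_SMILES_CHARS)
        for smi in smiles_iterable:
            tokens.update(tokenize_smiles(smi))
        return cls(smiles_tokens=tuple(sorted(tokens)), **bin_kwargs)

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for t in self.tokens:
            h.update(t.encode())
        return h.hexdigest()[:16]
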