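"""Discrete character state maps for tree tips.

Foot-type coding used throughout: 0 non-webbed, 1 palmate, 2 semipalmate,
3 totipalmate, 4 lobate. MISSING (``None``; ``?`` or ``-`` in TSV) marks a
taxon of unknown state, which contributes an all-ones conditional vector to
the likelihood (standard ambiguity handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, ValidationError

MISSING = None
MISSING_TOKENS = {"?", "-", "NA", ""}

FOOT_STATE_NAMES = ["non-webbed", "palmate", "semipalmate", "totipalmate", "lobate"]


@dataclass
class CharacterStateMap:
    """Mapping tip label -> state index in ``{0..k-1}`` or ``None`` (missing)."""

    states: dict
    k: int

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")
        for label, s in self.states.items():
            if s is None:
                continue
            if not (0 <= int(s) < self.k):
                raise ValidationError(f"state {s!r} for tip {label!r} out of range for k={self.k}")

    def __getitem__(self, label):
        return self.states[label]

    def __contains__(self, label):
        return label in self.states

    @property
    def n_observed(self) -> int:
        return sum(1 for s in self.states.values() if s is not None)

    def observed_states(self) -> set:
        return {int(s) for s in self.states.values() if s is not None}

    def relabelled(self, perm) -> "CharacterStateMap":
        """Apply a permutation of state indices (``perm[old] = new``)."""
        return CharacterStateMap(
            {t: (None if s is None else int(perm[int(s)])) for t, s in self.states.items()},
            self.k,
        )

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "CharacterStateMap":
        """Read a two-column ``tip<TAB>state`` table; ``?`` codes missing.

        If ``k`` is not given it is inferred as ``max(state) + 1`` (minimum 2).
        """
        path = Path(path)
        if not path.exists():
            raise InputError(f"states file not found: {path}")
        states: dict = {}
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected two tab-separated columns")
            label, tok = parts[0].strip(), parts[1].strip()
            if label in states:
                raise ValidationError(f"{path}:{ln}: duplicate tip label {label!r}")
            if tok in MISSING_TOKENS:
                states[label] = None
            else:
                try:
                    states[label] = int(tok)
                except ValueError:
                    raise InputError(f"{path}:{ln}: state {tok!r} is not an integer or '?'") from None
        if not states:
            raise InputError(f"{path}: no states found")
        if k is None:
            observed = [s for s in states.values() if s is not None]
            k = max(max(observed) + 1, 2) if observed else 2
        return cls(states, k)

    def to_tsv(self, path) -> None:
        lines = [f"{t}\t{'?' if s is None else s}" for t, s in self.states.items()]
        Path(path).write_text("\n".join(lines) + "\n")
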