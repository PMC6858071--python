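"""The nested lattice of model variants used in stepwise selection.

Selection experiments (growth in the presence of formaldehyde) always
estimate the death coefficient α and may add the tolerance-sensitivity b,
phenotypic diffusion D, and/or advection v.  Regrowth experiments
(formaldehyde-free medium, so no death) estimate only v and/or D.  Variant
names follow the scenario: F* for formaldehyde selection, M* for methanol
regrowth, S* for succinate regrowth, with the digit giving the number of
free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelVariant", "get_variant", "variant_for_free_set", "candidate_expansions"]

PARAMETERS = ("alpha", "b", "v", "D")


@dataclass(frozen=True)
class ModelVariant:
    name: str
    scenario: str  # "selection" or "regrowth"
    free: frozenset

    @property
    def n_free(self) -> int:
        return len(self.free)

    def nests(self, other: "ModelVariant") -> bool:
        """True if self is a reduced (nested) version of ``other``."""
        return self.scenario == other.scenario and self.free < other.free


def _v(name, scenario, *free):
    return ModelVariant(name, scenario, frozenset(free))


_SELECTION = [
    _v("F1", "selection", "alpha"),
    _v("F2a", "selection", "alpha", "b"),
    _v("F2b", "selection", "alpha", "v"),
    _v("F2c", "selection", "alpha", "D"),
    _v("F3a", "selection", "alpha", "b", "D"),
    _v("F3b", "selection", "alpha", "v", "D"),
    _v("F3c", "selection", "alpha", "b", "v"),
    _v("F4", "selection", "alpha", "b", "v", "D"),
]

# regrowth lattices are identical in structure; the prefix encodes substrate
_REGROWTH = {
    prefix: [
        _v(f"{prefix}0", "regrowth"),
        _v(f"{prefix}1a", "regrowth", "v"),
        _v(f"{prefix}1b", "regrowth", "D"),
        _v(f"{prefix}2", "regrowth", "v", "D"),
    ]
    for prefix in ("M", "S")
}

_ALL = {v.name: v for v in _SELECTION + _REGROWTH["M"] + _REGROWTH["S"]}


def get_variant(name: str) -> ModelVariant:
    try:
        return _ALL[name]
    except KeyError:
        raise KeyError(f"unknown model variant {name!r}; known: {sorted(_ALL)}") from None


def variant_for_free_set(scenario: str, free, substrate: str = "methanol") -> ModelVariant:
    """Look up the named variant with exactly the given free parameters."""
    free = frozenset(free)
    pool = _SELECTION if scenario == "selection" else _REGROWTH["S" if substrate == "succinate" else "M"]
    for v in pool:
        if v.free == free:
            return v
    raise KeyError(f"no {scenario} variant with free parameters {sorted(free)}")


def candidate_expansions(current: ModelVariant, substrate: str = "methanol") -> list[ModelVariant]:
    """All variants adding exactly one free parameter to ``current``."""
    if current.scenario == "selection":
        allowed = {"alpha", "b", "v", "D"}
    else:
        allowed = {"v", "D"}
    out = []
    for p in PARAMETERS:
        if p in allowed and p not in current.free:
            out.append(variant_for_free_set(current.scenario, current.free | {p}, substrate))
    return out
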