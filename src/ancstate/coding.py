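"""State spaces, per-taxon trait codings (polymorphism allowed) and transition-constraint masks.

Two built-in behavioral schemes are provided for the apid social-level character:

* ``traditional`` — four states (solitary, primitively eusocial, advanced
  eusocial, parasitic);
* ``complex`` — the same plus a fifth "social" state between solitary and
  primitively eusocial.

Both share the same biological constraint rules: no direct jump from solitary
or parasitic nesting to advanced eusociality, and no transition out of
advanced eusociality (an absorbing state, since advanced eusocial queens
cannot found nests without workers). Any other mask can be supplied per cell
in a scheme config.

Five binary life-history traits (two-generation colonies, castes with division
of labor, mass provisioning, morphologically undifferentiated castes, solitary
colony founding) are available as ``lifehistory:<trait>`` schemes: k = 2, full
mask, reversible-jump flag on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "State",
    "StateSpace",
    "TipStateMap",
    "TransitionConstraintMask",
    "CodingScheme",
    "SchemeError",
    "builtin_scheme",
    "load_scheme",
    "tip_partial",
    "validate_reachability",
    "read_trait_file",
    "write_trait_file",
    "LIFE_HISTORY_TRAITS",
    "SOCIAL_STATES",
]


class SchemeError(ValueError):
    """A coding scheme, trait file or mask is inconsistent."""


@dataclass(frozen=True)
class State:
    name: str        # long name, e.g. "primitively_eusocial"
    abbrev: str      # short label, e.g. "Prim"
    symbol: str      # single-character trait-file symbol, e.g. "2"


# the five social-level states, in fixed order; trait-file symbols are global
SOCIAL_STATES = (
    State("solitary", "Sol", "0"),
    State("social", "Soc", "1"),
    State("primitively_eusocial", "Prim", "2"),
    State("advanced_eusocial", "Adv", "3"),
    State("parasitic", "Paras", "4"),
)

LIFE_HISTORY_TRAITS = (
    "two_generations",
    "division_of_labor",
    "mass_provisioning",
    "undifferentiated_castes",
    "solitary_founding",
)


class StateSpace:
    """An ordered set of k >= 2 character states."""

    def __init__(self, states):
        self.states = tuple(states)
        if len(self.states) < 2:
            raise SchemeError("state space needs k >= 2 states")
        if len({s.abbrev for s in self.states}) != len(self.states) or len(
            {s.symbol for s in self.states}
        ) != len(self.states):
            raise SchemeError("state abbreviations/symbols must be unique")
        self._by_abbrev = {s.abbrev: i for i, s in enumerate(self.states)}
        self._by_symbol = {s.symbol: i for i, s in enumerate(self.states)}

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def abbrevs(self) -> tuple:
        return tuple(s.abbrev for s in self.states)

    def index(self, key: str) -> int:
        """Index of a state by abbreviation, long name or symbol."""
        if key in self._by_abbrev:
            return self._by_abbrev[key]
        if key in self._by_symbol:
            return self._by_symbol[key]
        for i, s in enumerate(self.states):
            if s.name == key:
                return i
        raise SchemeError(f"unknown state {key!r}; states are {self.abbrevs}")

    def indicator(self, keys) -> np.ndarray:
        v = np.zeros(self.k)
        for key in keys:
            v[self.index(key)] = 1.0
        return v

    def __len__(self) -> int:
        return self.k

    def __iter__(self):
        return iter(self.states)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StateSpace({', '.join(self.abbrevs)})"


class TransitionConstraintMask:
    """k x k boolean matrix; ``allowed[i, j]`` (i != j) marks a permitted i -> j transition."""

    def __init__(self, space: StateSpace, allowed: np.ndarray):
        allowed = np.asarray(allowed, dtype=bool).copy()
        if allowed.shape != (space.k, space.k):
            raise SchemeError(
                f"mask shape {allowed.shape} does not match state space k={space.k}"
            )
        np.fill_diagonal(allowed, False)  # diagonal ignored
        self.space = space
        self.allowed = allowed

    @classmethod
    def full(cls, space: StateSpace) -> "TransitionConstraintMask":
        return cls(space, ~np.eye(space.k, dtype=bool))

    @classmethod
    def from_rules(cls, space: StateSpace, forbidden) -> "TransitionConstraintMask":
        """Build a mask from a list of forbidden moves ``("From", "To")``; "*" is a wildcard."""
        allowed = ~np.eye(space.k, dtype=bool)
        for frm, to in forbidden:
            rows = range(space.k) if frm == "*" else [space.index(frm)]
            cols = range(space.k) if to == "*" else [space.index(to)]
            for i in rows:
                for j in cols:
                    if i != j:
                        allowed[i, j] = False
        return cls(space, allowed)

    @property
    def n_allowed(self) -> int:
        return int(self.allowed.sum())

    def allowed_cells(self) -> list[tuple[int, int]]:
        """Row-major list of allowed off-diagonal cells: the free-rate layout."""
        return [(i, j) for i in range(self.space.k) for j in range(self.space.k)
                if self.allowed[i, j]]

    def reachable_from(self, sources) -> set:
        """State indices reachable (in >= 0 steps) from ``sources`` on the directed mask graph."""
        seen = set(sources)
        stack = list(sources)
        while stack:
            i = stack.pop()
            for j in range(self.space.k):
                if self.allowed[i, j] and j not in seen:
                    seen.add(j)
                    stack.append(j)
        return seen


class TipStateMap(dict):
    """taxon -> nonempty frozenset of state indices (size > 1 = polymorphic/uncertain)."""

    def __init__(self, space: StateSpace, mapping=None):
        super().__init__()
        self.space = space
        for taxon, states in (mapping or {}).items():
            self.set_states(taxon, states)

    def set_states(self, taxon: str, states) -> None:
        if isinstance(states, str):
            if states == "-":
                idx = frozenset(range(self.space.k))
            else:
                idx = frozenset(self.space.index(ch) for ch in states)
        else:
            idx = frozenset(
                s if isinstance(s, (int, np.integer)) else self.space.index(s)
                for s in states
            )
        if not idx:
            raise SchemeError(f"taxon {taxon!r} has an empty state set")
        self[taxon] = idx

    def symbols(self, taxon: str) -> str:
        return "".join(self.space.states[i].symbol for i in sorted(self[taxon]))


@dataclass
class CodingScheme:
    """A named character: state space + tip codings + constraint mask (+ RJ flag)."""

    name: str
    space: StateSpace
    tips: TipStateMap
    mask: TransitionConstraintMask
    rj: bool = False

    def __post_init__(self):
        if self.mask.space.k != self.space.k:
            raise SchemeError("mask dimensions do not match state space")

    def check_taxa(self, taxa) -> None:
        missing = sorted(set(taxa) - set(self.tips))
        if missing:
            raise SchemeError(
                f"scheme {self.name!r} lacks codings for taxa: {missing}"
            )


# ---------------------------------------------------------------------------
# built-ins

#: the two quoted constraint rules: (a) no solitary/parasitic -> advanced jump,
#: (b) advanced eusociality is absorbing
_CONSTRAINT_RULES = [("Sol", "Adv"), ("Paras", "Adv"), ("Adv", "*")]


def _social_space(with_social: bool) -> StateSpace:
    if with_social:
        return StateSpace(SOCIAL_STATES)
    return StateSpace([s for s in SOCIAL_STATES if s.abbrev != "Soc"])


def builtin_scheme(name: str, tips: TipStateMap | dict | None = None) -> CodingScheme:
    """Construct a built-in scheme: ``traditional``, ``complex`` or ``lifehistory:<trait>``.

    Tip codings may be attached afterwards (``scheme.tips``) or passed here.
    """
    if name == "traditional":
        space = _social_space(with_social=False)
        mask = TransitionConstraintMask.from_rules(space, _CONSTRAINT_RULES)
        rj = False
    elif name == "complex":
        space = _social_space(with_social=True)
        mask = TransitionConstraintMask.from_rules(space, _CONSTRAINT_RULES)
        rj = False
    elif name.startswith("lifehistory:"):
        trait = name.split(":", 1)[1]
        if trait not in LIFE_HISTORY_TRAITS:
            raise SchemeError(
                f"unknown life-history trait {trait!r}; options: {LIFE_HISTORY_TRAITS}"
            )
        space = StateSpace([State("absent", "abs", "0"), State("present", "pres", "1")])
        mask = TransitionConstraintMask.full(space)
        rj = True
    else:
        raise SchemeError(f"unknown built-in scheme {name!r}")
    tipmap = tips if isinstance(tips, TipStateMap) else TipStateMap(space, tips or {})
    if tipmap.space.k != space.k:
        raise SchemeError("tip map state space does not match scheme")
    return CodingScheme(name, space, tipmap, mask, rj)


def load_scheme(source) -> CodingScheme:
    """Load a CodingScheme from a YAML file path, YAML string, or dict.

    Keys: ``name`` (optional; a built-in name pulls its space+mask), ``states``
    (list of [name, abbrev, symbol] or abbrevs), ``forbidden`` (list of
    ``"From->To"``), ``tips`` (taxon: symbol string), ``rj`` (bool).
    """
    if isinstance(source, dict):
        cfg = source
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemeError("scheme config must be a mapping")

    name = cfg.get("name", "custom")
    if name in ("traditional", "complex") or str(name).startswith("lifehistory:"):
        scheme = builtin_scheme(name)
        space, mask, rj = scheme.space, scheme.mask, scheme.rj
    else:
        raw = cfg.get("states")
        if not raw:
            raise SchemeError("custom scheme config needs a 'states' list")
        states = []
        for i, entry in enumerate(raw):
            if isinstance(entry, (list, tuple)) and len(entry) == 3:
                states.append(State(*entry))
            else:
                states.append(State(str(entry), str(entry), str(i)))
        space = StateSpace(states)
        mask = TransitionConstraintMask.full(space)
        rj = False

    if "forbidden" in cfg:
        rules = []
        for item in cfg["forbidden"]:
            try:
                frm, to = [part.strip() for part in item.split("->")]
            except ValueError:
                raise SchemeError(f"bad forbidden entry {item!r}; expected 'From->To'")
            rules.append((frm, to))
        mask = TransitionConstraintMask.from_rules(space, rules)
    rj = bool(cfg.get("rj", rj))

    tips = TipStateMap(space)
    for taxon, symbols in (cfg.get("tips") or {}).items():
        tips.set_states(str(taxon), str(symbols))
    return CodingScheme(str(name), space, tips, mask, rj)


# ---------------------------------------------------------------------------
# operations


def tip_partial(taxon: str, scheme: CodingScheme) -> np.ndarray:
    """Length-k 0/1 indicator of the taxon's allowed states (ambiguity semantics)."""
    if taxon not in scheme.tips:
        raise KeyError(f"taxon {taxon!r} has no coding in scheme {scheme.name!r}")
    v = np.zeros(scheme.space.k)
    for i in scheme.tips[taxon]:
        v[i] = 1.0
    return v


def validate_reachability(scheme: CodingScheme, root_prior=None) -> list[str]:
    """Warnings for observed tip states unreachable from every root state with support.

    An unreachable observed state forces a zero likelihood; this is reported,
    not raised, because fossilized analyses may create it deliberately.
    """
    k = scheme.space.k
    if root_prior is None:
        sources = set(range(k))
    else:
        root_prior = np.asarray(root_prior, dtype=float)
        sources = {i for i in range(k) if root_prior[i] > 0}
    reachable = scheme.mask.reachable_from(sources)
    observed = set()
    for states in scheme.tips.values():
        observed |= set(states)
    warnings = []
    for s in sorted(observed - reachable):
        warnings.append(
            f"state {scheme.space.abbrevs[s]!r} is observed at tips but unreachable "
            "from every root state with nonzero prior; the likelihood will be 0"
        )
    return warnings


# ---------------------------------------------------------------------------
# trait files (two-column tab-delimited, BayesTraits style)


def read_trait_file(path, space: StateSpace) -> TipStateMap:
    tips = TipStateMap(space)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemeError(
                    f"{path}:{ln}: expected 'taxon<TAB>states', got {line!r}"
                )
            taxon, symbols = parts
            if taxon in tips:
                raise SchemeError(f"{path}:{ln}: duplicate taxon {taxon!r}")
            tips.set_states(taxon, symbols.strip())
    return tips


def write_trait_file(tips: TipStateMap, path) -> None:
    with open(path, "w") as fh:
        for taxon in tips:
            fh.write(f"{taxon}\t{tips.symbols(taxon)}\n")
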