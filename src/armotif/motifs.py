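"""Position-class grammar for the ankyrin-repeat-binding ΨβXXQP motif.

The AR (ankyrin repeat) domains of the Golgi S-acyltransferases zDHHC17 and
zDHHC13 recognize a six-residue short linear motif of the form ΨβXXQP, where

* Ψ is an aliphatic residue — Val, Ile, Ala or Pro, but explicitly *not* Leu;
* β is a C-beta-branched residue — Val, Ile or Thr;
* X is any standard amino acid;
* the final two positions are an invariant Gln-Pro pair.

The consensus splits into three mutually exclusive submotifs:

* ``[VIA][VI]XXQP`` — the common form;
* ``P[VI][VIL]XQP`` — when Pro occupies Ψ, the third position is also
  restricted to an aliphatic residue;
* ``Q[VI]TXXQP`` — when Thr occupies β, a Gln is required immediately
  upstream of the six-residue core (the context residue is *not* part of the
  reported hit coordinates; every hit stays six residues long).

A "relaxed" terminal mode models the observation that Val or Ile at the
final position partially preserves binding while Gly/Ser/Thr do not: such
windows are reported with a ``partial`` qualifier rather than as full hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues granted "partial" status at the terminal Pro in relaxed mode.
RELAXED_TERMINAL = frozenset({"V", "I"})


@dataclass(frozen=True)
class PositionClass:
    """One motif position: a label and the set of residues it accepts."""

    label: str
    allowed: frozenset

    def __post_init__(self):
        allowed = frozenset(str(r).upper() for r in self.allowed)
        if not allowed:
            raise ValueError(f"position class {self.label!r} allows no residue")
        if not allowed <= STANDARD_AA:
            bad = sorted(allowed - STANDARD_AA)
            raise ValueError(
                f"position class {self.label!r} contains non-standard residues {bad}"
            )
        object.__setattr__(self, "allowed", allowed)

    def accepts(self, residue: str) -> bool:
        """True iff *residue* (uppercased) is in this class.

        Non-standard letters (B, Z, X, U, J, O, ``*`` …) never match any
        class; they are treated as data to skip, not as errors.
        """
        return residue.upper() in self.allowed


def _cls(label: str, residues: Iterable[str]) -> PositionClass:
    return PositionClass(label, frozenset(residues))


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered run of position classes, with optional upstream context.

    ``core`` is the six-position pattern whose span is reported as the hit;
    ``upstream_context``, when present, constrains the residue immediately
    before the core (used only by the Q[VI]TXXQP submotif).
    """

    name: str
    core: tuple
    upstream_context: Optional[PositionClass] = None
    terminal_relaxed_allowed: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "core", tuple(self.core))
        if not self.core:
            raise ValueError("motif core must have at least one position")
        object.__setattr__(
            self, "terminal_relaxed_allowed", frozenset(self.terminal_relaxed_allowed)
        )

    def __len__(self) -> int:
        return len(self.core)

    def relaxed(self, residues: Iterable[str] = RELAXED_TERMINAL) -> "MotifDefinition":
        """Copy of this definition with a relaxed terminal position."""
        return replace(self, terminal_relaxed_allowed=frozenset(residues))


# --- bundled definitions ---------------------------------------------------

def build_general_consensus() -> MotifDefinition:
    """The general ΨβXXQP consensus: [VIAP][VIT]XXQP."""
    return MotifDefinition(
        name="general",
        core=(
            _cls("Ψ", "VIAP"),
            _cls("β", "VIT"),
            _cls("X", STANDARD_AA),
            _cls("X", STANDARD_AA),
            _cls("Q", "Q"),
            _cls("P", "P"),
        ),
    )


def build_submotifs() -> list:
    """The three submotifs, pairwise exclusive restrictions of the consensus."""
    sub1 = MotifDefinition(
        name="[VIA][VI]xxQP",
        core=(
            _cls("Ψ", "VIA"),
            _cls("β", "VI"),
            _cls("X", STANDARD_AA),
            _cls("X", STANDARD_AA),
            _cls("Q", "Q"),
            _cls("P", "P"),
        ),
    )
    sub2 = MotifDefinition(
        name="P[VI][VIL]xQP",
        core=(
            _cls("Ψ", "P"),
            _cls("β", "VI"),
            _cls("X", "VIL"),
            _cls("X", STANDARD_AA),
            _cls("Q", "Q"),
            _cls("P", "P"),
        ),
    )
    sub3 = MotifDefinition(
        name="Q[VI]TxxQP",
        core=(
            _cls("Ψ", "VI"),
            _cls("β", "T"),
            _cls("X", STANDARD_AA),
            _cls("X", STANDARD_AA),
            _cls("Q", "Q"),
            _cls("P", "P"),
        ),
        upstream_context=_cls("Q", "Q"),
    )
    return [sub1, sub2, sub3]


def bundled_definitions(which: str = "all") -> list:
    """Return the bundled motif definitions.

    Parameters
    ----------
    which:
        ``"general"``, ``"submotifs"`` or ``"all"`` (general first).
    """
    if which == "general":
        return [build_general_consensus()]
    if which == "submotifs":
        return build_submotifs()
    if which == "all":
        return [build_general_consensus()] + build_submotifs()
    raise ValueError(f"unknown motif set {which!r}")


# --- window matching -------------------------------------------------------

@dataclass(frozen=True)
class WindowMatch:
    """Outcome of evaluating one definition against one window."""

    matched: bool
    qualifier: Optional[str] = None  # "full" | "partial"
    context_ok: bool = True          # meaningful when upstream_context set
    core_ok: bool = False            # core classes matched irrespective of context


def evaluate_window(
    definition: MotifDefinition, window: str, upstream: Optional[str] = None
) -> WindowMatch:
    """Evaluate *window* (and the optional upstream residue) against a definition.

    ``matched`` requires every core position to be in class — or, if the
    definition carries a relaxed terminal set, all but the last, with the
    last in the relaxed set (``qualifier="partial"``) — and, when an
    upstream context class is defined, an upstream residue that satisfies it.
    """
    if len(window) != len(definition):
        raise ValueError(
            f"window length {len(window)} != motif length {len(definition)}"
        )
    window = window.upper()
    head_ok = all(
        cls.accepts(res) for cls, res in zip(definition.core[:-1], window[:-1])
    )
    last_cls = definition.core[-1]
    last = window[-1]
    if not head_ok:
        qualifier = None
    elif last_cls.accepts(last):
        qualifier = "full"
    elif last.upper() in definition.terminal_relaxed_allowed:
        qualifier = "partial"
    else:
        qualifier = None
    core_ok = qualifier is not None
    context_ok = True
    if definition.upstream_context is not None:
        context_ok = upstream is not None and definition.upstream_context.accepts(
            upstream
        )
    return WindowMatch(
        matched=core_ok and context_ok,
        qualifier=qualifier if (core_ok and context_ok) else None,
        context_ok=context_ok,
        core_ok=core_ok,
    )


def matches_window(
    definition: MotifDefinition, window: str, upstream: Optional[str] = None
) -> bool:
    """True iff the window is a *full* match of the definition.

    Wrong window length raises ``ValueError``; non-standard residue letters
    simply fail their class.
    """
    m = evaluate_window(definition, window, upstream)
    return m.matched and m.qualifier == "full"


# --- plain-text serialization ---------------------------------------------
#
# Format (one block per motif, blank-line separated):
#
#   motif <name>
#   context <residues>          # optional
#   pos <i> <residues>          # one line per core position, 1-based
#
# Users can add custom motifs by writing such a file and loading it with
# definitions_from_text().

def definitions_to_text(definitions: Iterable[MotifDefinition]) -> str:
    blocks = []
    for d in definitions:
        lines = [f"motif {d.name}"]
        if d.upstream_context is not None:
            lines.append("context " + "".join(sorted(d.upstream_context.allowed)))
        for i, cls in enumerate(d.core, start=1):
            lines.append(f"pos {i} " + "".join(sorted(cls.allowed)))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def definitions_from_text(text: str) -> list:
    definitions = []
    name = None
    context = None
    positions = {}

    def flush():
        nonlocal name, context, positions
        if name is None:
            return
        if not positions:
            raise ValueError(f"motif {name!r} has no positions")
        idx = sorted(positions)
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"motif {name!r} positions not contiguous from 1")
        core = tuple(_cls(f"p{i}", positions[i]) for i in idx)
        definitions.append(
            MotifDefinition(name=name, core=core, upstream_context=context)
        )
        name, context, positions = None, None, {}

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "motif":
            flush()
            name = " ".join(tok[1:])
            if not name:
                raise ValueError("motif line without a name")
        elif tok[0] == "context":
            context = _cls("context", tok[1])
        elif tok[0] == "pos":
            positions[int(tok[1])] = tok[2]
        else:
            raise ValueError(f"unrecognized motif-config line: {raw!r}")
    flush()
    if not definitions:
        raise ValueError("no motif definitions found")
    return definitions
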