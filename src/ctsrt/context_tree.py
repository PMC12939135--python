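"""Probabilistic context trees (variable-length Markov chains) for stimulus generation.

A context tree is a suffix-free set of finite histories ("contexts"), each
carrying a probability distribution over the next symbol.  The serial
reaction time task studied here uses a three-symbol tree over {1, 2, 3}:

    context (1,)    -> 2 with probability 1          (the following 2 is "fixed",   F2)
    context (1, 2)  -> 2 with p = 0.26, 3 with 0.74  ("variable" events V2 and V3)
    context (2, 2)  -> 1 with probability 1          (F1)
    context (3,)    -> 1 with probability 1          (F1)

Every generated symbol is labelled by the determinism of the context that
emitted it (F = fixed, V = variable) plus the symbol itself, and each trial
additionally records the most recent strictly-preceding variable event
("last variable event"), the conditioning factor of the downstream analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

Symbol = int
Context = tuple[Symbol, ...]

#: sentinel event labels
UNKNOWN = "UNKNOWN"
NO_LAST_VAR = "NONE"

_PROB_TOL = 1e-12


class InvalidTreeError(ValueError):
    """The tree cannot generate / be analysed (structural defect)."""


class AnalyticError(RuntimeError):
    """The induced context chain does not admit a unique stationary law."""


@dataclass(frozen=True)
class ContextTree:
    """A finite context tree: alphabet, contexts and per-context transition laws.

    ``transitions`` maps each context (a tuple of symbols, oldest first) to a
    probability vector aligned with ``alphabet`` order.
    """

    alphabet: tuple[Symbol, ...]
    transitions: dict[Context, tuple[float, ...]] = field(hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        object.__setattr__(
            self,
            "transitions",
            {tuple(k): tuple(float(p) for p in v) for k, v in self.transitions.items()},
        )

    @property
    def contexts(self) -> list[Context]:
        return sorted(self.transitions, key=lambda c: (len(c), c))

    @property
    def max_depth(self) -> int:
        return max((len(c) for c in self.transitions), default=0)

    def is_deterministic(self, context: Context) -> bool:
        """True when the context emits a single symbol with probability one."""
        return max(self.transitions[tuple(context)]) >= 1.0 - _PROB_TOL

    def symbol_probability(self, context: Context, symbol: Symbol) -> float:
        return self.transitions[tuple(context)][self.alphabet.index(symbol)]

    # ---------------------------------------------------------------- JSON I/O
    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet),
            "contexts": {
                ",".join(map(str, ctx)): list(probs)
                for ctx, probs in sorted(self.transitions.items())
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ContextTree":
        alphabet = tuple(int(a) for a in payload["alphabet"])
        transitions = {}
        for key, probs in payload["contexts"].items():
            ctx = tuple(int(s) for s in key.split(",")) if key else ()
            transitions[ctx] = tuple(float(p) for p in probs)
        return cls(alphabet=alphabet, transitions=transitions)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ContextTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_tree() -> ContextTree:
    """The packaged three-symbol task tree (shipped as ``data/srt_tree.json``)."""
    with resources.files("ctsrt.data").joinpath("srt_tree.json").open() as fh:
        return ContextTree.from_dict(json.load(fh))


# --------------------------------------------------------------------- checks
def validate_tree(tree: ContextTree) -> list[str]:
    """Return all invariant violations (empty list when the tree is valid).

    Checks probability normalisation, suffix-freeness of the context set and
    completeness (every history reachable under the transitions matches a
    context).  Violations are returned as data, not raised.
    """
    report: list[str] = []
    k = len(tree.alphabet)
    if k == 0:
        report.append("alphabet is empty")
    if not tree.transitions:
        report.append("context set is empty")
        return report

    for ctx, probs in tree.transitions.items():
        if len(probs) != k:
            report.append(f"context {ctx}: probability vector length {len(probs)} != {k}")
            continue
        if any(p < 0 for p in probs):
            report.append(f"context {ctx}: negative probability")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            report.append(f"context {ctx}: probabilities sum to {sum(probs)!r}, not 1")
        if any(s not in tree.alphabet for s in ctx):
            report.append(f"context {ctx}: symbol outside alphabet")

    ctxs = list(tree.transitions)
    for a in ctxs:
        for b in ctxs:
            if a != b and len(a) < len(b) and b[len(b) - len(a):] == a:
                report.append(f"context {a} is a proper suffix of context {b}")

    # completeness: the context chain must be closed under positive transitions
    for ctx, probs in tree.transitions.items():
        if len(probs) != k:
            continue
        for sym, p in zip(tree.alphabet, probs):
            if p > 0 and _match(tree, ctx + (sym,)) is None:
                report.append(
                    f"incomplete: history {ctx + (sym,)} reachable from {ctx} "
                    "matches no context"
                )
    return report


# ------------------------------------------------------------------- matching
def _match(tree: ContextTree, history: Sequence[Symbol]) -> Context | None:
    """Longest-suffix context lookup on a (bounded) history; None when unmatched."""
    h = tuple(history[-tree.max_depth:]) if tree.max_depth else ()
    for length in range(len(h), -1, -1):
        ctx = h[len(h) - length:]
        if ctx in tree.transitions:
            return ctx
    return None


def match_context(tree: ContextTree, history: Sequence[Symbol]) -> Context | None:
    """Return the unique context that is a suffix of ``history`` (None if no match).

    Suffix-freeness guarantees at most one context matches; short leading
    histories may match none.
    """
    history = tuple(history)
    bad = [s for s in history if s not in tree.alphabet]
    if bad:
        raise ValueError(f"symbols outside alphabet {tree.alphabet}: {sorted(set(bad))}")
    return _match(tree, history)


# ----------------------------------------------------------------- generation
def generate_sequence(
    tree: ContextTree,
    n: int,
    seed: int | None = None,
    initial: Iterable[Symbol] = (1,),
    burn_in: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate ``n`` symbols from the tree, starting from ``initial``.

    The draw is deterministic given the seed: exactly one uniform variate is
    consumed per variable-context emission and none for deterministic
    contexts (a fully deterministic tree is seed-independent).  ``burn_in``
    extra leading symbols are generated and discarded when requested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    problems = validate_tree(tree)
    if problems:
        raise InvalidTreeError("; ".join(problems))

    # per-context samplers: deterministic symbol, or (cdf, symbols)
    samplers: dict[Context, tuple] = {}
    for ctx, probs in tree.transitions.items():
        arr = np.asarray(probs)
        if arr.max() >= 1.0 - _PROB_TOL:
            samplers[ctx] = (True, tree.alphabet[int(arr.argmax())])
        else:
            keep = arr > 0
            samplers[ctx] = (False, np.cumsum(arr[keep]), np.asarray(tree.alphabet)[keep])

    seq = list(initial)
    if not all(s in tree.alphabet for s in seq):
        raise ValueError("initial contains symbols outside the alphabet")
    total = n + burn_in
    maxd = tree.max_depth
    match_cache: dict[Context, Context | None] = {}
    while len(seq) < total:
        state = tuple(seq[-maxd:])
        ctx = match_cache.get(state, False)
        if ctx is False:
            ctx = _match(tree, state)
            match_cache[state] = ctx
        if ctx is None:
            raise InvalidTreeError(
                f"no context matches history suffix {state}; "
                "initial string does not resolve to a matchable context"
            )
        sampler = samplers[ctx]
        if sampler[0]:
            seq.append(sampler[1])
        else:
            u = rng.random()
            seq.append(int(sampler[2][int(np.searchsorted(sampler[1], u))]))
    return np.asarray(seq[burn_in:burn_in + n], dtype=int)


# ------------------------------------------------------------------- labelling
def event_label(tree: ContextTree, context: Context, symbol: Symbol) -> str:
    """F<sym> when the emitting context is deterministic, else V<sym>."""
    return ("F" if tree.is_deterministic(context) else "V") + str(symbol)


def label_events(tree: ContextTree, symbols: Sequence[Symbol]) -> list[str]:
    """Label each position by the determinism of its emitting context.

    Positions whose history matches no context are UNKNOWN, except a leading
    symbol 1, which is labelled F1: a session starts at the triplet-initial
    fixed event, and this keeps the per-block event counts exact.
    """
    symbols = list(symbols)
    labels: list[str] = []
    maxd = tree.max_depth
    for t, s in enumerate(symbols):
        if s not in tree.alphabet:
            raise ValueError(f"symbol {s!r} outside alphabet {tree.alphabet}")
        ctx = _match(tree, symbols[max(0, t - maxd):t])
        if ctx is None:
            labels.append("F1" if (t == 0 and s == 1) else UNKNOWN)
            continue
        if tree.symbol_probability(ctx, s) == 0.0:
            warnings.warn(
                f"symbol {s} at position {t} has zero probability under matched "
                f"context {ctx}; label assigned by symbol",
                stacklevel=2,
            )
        labels.append(event_label(tree, ctx, s))
    return labels


def annotate_last_variable(labels: Sequence[str]) -> list[str]:
    """Most recent strictly-preceding V-label per position (NONE before the first)."""
    out: list[str] = []
    last = NO_LAST_VAR
    for lab in labels:
        out.append(last)
        if lab.startswith("V"):
            last = lab
    return out


# ------------------------------------------------------------------ stationary
def _context_chain(tree: ContextTree):
    ctxs = tree.contexts
    index = {c: i for i, c in enumerate(ctxs)}
    P = np.zeros((len(ctxs), len(ctxs)))
    emissions = []  # (i, j, symbol, prob)
    for c in ctxs:
        for sym, p in zip(tree.alphabet, tree.transitions[c]):
            if p <= 0:
                continue
            nxt = _match(tree, c + (sym,))
            if nxt is None:
                raise InvalidTreeError(f"history {c + (sym,)} matches no context")
            P[index[c], index[nxt]] += p
            emissions.append((index[c], sym, p))
    return ctxs, P, emissions


def stationary_event_frequencies(tree: ContextTree) -> dict[str, float]:
    """Long-run frequency of each event label, from the induced context chain.

    Solves pi P = pi for the Markov chain on contexts and accumulates the
    emission law per context.  Raises :class:`AnalyticError` when the chain is
    not irreducible (no unique stationary distribution).
    """
    problems = validate_tree(tree)
    if problems:
        raise InvalidTreeError("; ".join(problems))
    ctxs, P, emissions = _context_chain(tree)
    n_comp, _ = connected_components(P > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise AnalyticError(
            f"induced context chain is reducible ({n_comp} strongly connected "
            "components); stationary frequencies are not unique"
        )
    # left eigenvector of P for eigenvalue 1
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[i] - 1.0) > 1e-8:
        raise AnalyticError("no unit eigenvalue found for the context chain")
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    freqs: dict[str, float] = {}
    for i_ctx, sym, p in emissions:
        lab = event_label(tree, ctxs[i_ctx], sym)
        freqs[lab] = freqs.get(lab, 0.0) + float(pi[i_ctx] * p)
    return freqs


def expected_event_counts(tree: ContextTree, n: int) -> dict[str, float]:
    """Expected number of each event label in ``n`` trials (n x stationary frequency)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return {lab: n * f for lab, f in stationary_event_frequencies(tree).items()}
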