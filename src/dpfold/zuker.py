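"""Minimum free energy folding over a pluggable loop-energy model, with traceback.

Two tables drive the recursion. ``V(i, j)`` is the optimal energy given that
(i, j) is paired, minimized over the loop it closes:

    E1  hairpin(i, j)
    E2  stack(i, j) + V(i+1, j-1)
    E3  min over interior/bulge closings (i', j'),
        i < i' < j' < j and (i'-i) + (j-j') > 2:  internal(i,j,i',j') + V(i',j')
    E4  multiloop: a + min over i < k < j-1 of WM(i+1, k) + WM(k+1, j-1)

``W(i, j)`` is the unconstrained optimum:

    W(i, i) = 0;  W(i, j) = min{ V(i,j); W(i+1,j); W(i,j-1);
                                 min over i < k < j-1 of W(i,k) + W(k+1,j) }

``WM`` is the multibranch helper (the recursion's auxiliary table; affine
parameters a/b/c all default to 0, which reduces E4 to a plain split over
paired content):

    WM(i, j) = min{ WM(i,j-1) + c; WM(i+1,j) + c; V(i,j) + b;
                    min over i <= k < j of WM(i,k) + WM(k+1,j) }

Cells whose span is below ``min_span`` are forbidden for pairing (V = inf)
but still carry the empty structure, so W is 0 there and the boundary
behaves like an empty-interval extension.

No published thermodynamic parameter table ships with this package; the
energy model is a pluggable contract.  :func:`default_energy_model` provides
a simple, documented stand-in (pair-strength stacks, logarithmic loop
penalties); real parameter sets can be loaded from a YAML file with
:func:`load_energy_model`.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, List, Optional, Tuple, Union

import yaml

from .core import BasePair, FoldConfig, RnaSequence, SecondaryStructure, can_pair
from .engine import FORBIDDEN, AuxiliaryStorage, DpState, FoldStrategy, PredictionResult
from . import engine
from .errors import DomainError

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Energy models
# ---------------------------------------------------------------------------


class EnergyModel:
    """Loop-energy function set: hairpin, stack, interior/bulge, affine multiloop.

    ``pair_energy`` is the per-pair pseudo-energy used by the partition
    strategy; ``rt`` is the thermodynamic scale (kcal/mol).
    """

    multiloop_a: float = 0.0
    multiloop_b: float = 0.0
    multiloop_c: float = 0.0
    rt: float = 0.616

    def hairpin(self, seq: RnaSequence, i: int, j: int) -> float:
        raise NotImplementedError

    def stack(self, seq: RnaSequence, i: int, j: int) -> float:
        """Energy of pair (i, j) stacked on (i+1, j-1)."""
        raise NotImplementedError

    def internal(self, seq: RnaSequence, i: int, j: int, ip: int, jp: int) -> float:
        """Energy of the interior/bulge loop between closing pairs (i,j) and (ip,jp)."""
        raise NotImplementedError

    def pair_energy(self, seq: RnaSequence, i: int, j: int) -> float:
        return 0.0


def _as_fn(v: Union[float, Callable[..., float]]) -> Callable[..., float]:
    if callable(v):
        return v
    return lambda *args, _v=float(v): _v


class ToyEnergyModel(EnergyModel):
    """Constant-or-callable model family used by the oracle test suites."""

    def __init__(
        self,
        hairpin: Union[float, Callable] = 0.0,
        stack: Union[float, Callable] = 0.0,
        internal: Union[float, Callable] = 0.0,
        multiloop_a: float = 0.0,
        multiloop_b: float = 0.0,
        multiloop_c: float = 0.0,
        pair_energy: Union[float, Callable] = 0.0,
        rt: float = 0.616,
    ):
        self._hairpin = _as_fn(hairpin)
        self._stack = _as_fn(stack)
        self._internal = _as_fn(internal)
        self._pair_energy = _as_fn(pair_energy)
        self.multiloop_a = multiloop_a
        self.multiloop_b = multiloop_b
        self.multiloop_c = multiloop_c
        self.rt = rt

    def hairpin(self, seq, i, j):
        return self._hairpin(seq, i, j)

    def stack(self, seq, i, j):
        return self._stack(seq, i, j)

    def internal(self, seq, i, j, ip, jp):
        return self._internal(seq, i, j, ip, jp)

    def pair_energy(self, seq, i, j):
        return self._pair_energy(seq, i, j)


#: Ad-hoc default parameters (NOT a published thermodynamic set): stack
#: bonuses scale with pair strength (GC > AU > GU), loop penalties grow
#: logarithmically with loop size, multiloops carry a small affine cost.
DEFAULT_ENERGY_PARAMS: Dict = {
    "rt": 0.616,
    "pair_strength": {"GC": 3.0, "AU": 2.0, "GU": 1.0},
    "stack_base": -1.0,  # stack = stack_base * (strength(outer)+strength(inner)) / 2
    "hairpin": {"base": 3.0, "slope": 1.3},  # base + slope * ln(loop_size / 3)
    "interior": {"base": 2.0, "slope": 1.1},  # base + slope * ln(loop_size / 2)
    "bulge": {"base": 2.5, "slope": 1.1},
    "multiloop": {"a": 3.4, "b": 0.4, "c": 0.0},
    "pair_energy": {"GC": -3.0, "AU": -2.0, "GU": -1.0},
}


class TableEnergyModel(EnergyModel):
    """Energy model driven by a parameter dictionary (see DEFAULT_ENERGY_PARAMS)."""

    def __init__(self, params: Optional[Dict] = None):
        p = dict(DEFAULT_ENERGY_PARAMS)
        if params:
            p.update(params)
        self.params = p
        self.rt = float(p["rt"])
        ml = p["multiloop"]
        self.multiloop_a = float(ml["a"])
        self.multiloop_b = float(ml["b"])
        self.multiloop_c = float(ml["c"])

    def _strength(self, a: str, b: str) -> float:
        key = "".join(sorted((a, b)))
        table = {"".join(sorted(k)): v for k, v in self.params["pair_strength"].items()}
        return float(table.get(key, 0.0))

    def hairpin(self, seq, i, j):
        size = j - i - 1
        h = self.params["hairpin"]
        return float(h["base"]) + float(h["slope"]) * math.log(max(size, 3) / 3.0)

    def stack(self, seq, i, j):
        outer = self._strength(seq.base(i), seq.base(j))
        inner = self._strength(seq.base(i + 1), seq.base(j - 1))
        return float(self.params["stack_base"]) * (outer + inner) / 2.0

    def internal(self, seq, i, j, ip, jp):
        left, right = ip - i - 1, j - jp - 1
        size = left + right
        kind = "bulge" if min(left, right) == 0 else "interior"
        t = self.params[kind]
        return float(t["base"]) + float(t["slope"]) * math.log(max(size, 2) / 2.0)

    def pair_energy(self, seq, i, j):
        key = "".join(sorted((seq.base(i), seq.base(j))))
        table = {"".join(sorted(k)): v for k, v in self.params["pair_energy"].items()}
        return float(table.get(key, 0.0))


def default_energy_model() -> TableEnergyModel:
    return TableEnergyModel()


def load_energy_model(path: str) -> TableEnergyModel:
    """Load parameter overrides from a YAML key-value file."""
    with open(path) as fh:
        params = yaml.safe_load(fh) or {}
    if not isinstance(params, dict):
        raise DomainError(f"energy parameter file {path} must hold a mapping")
    return TableEnergyModel(params)


# ---------------------------------------------------------------------------
# Fill / traceback
# ---------------------------------------------------------------------------


class ZukerState:
    """W / V tables plus the auxiliary multibranch table WM."""

    def __init__(self, n: int, em: EnergyModel, audit: bool = False):
        self.n = n
        self.em = em
        self.W = DpState(n, name="W", audit=audit)
        self.V = DpState(n, name="V", audit=audit)
        self.WM = DpState(n, name="WM", audit=audit)
        self.aux = AuxiliaryStorage(kind="free_energy_op", payload=em)

    def w(self, i: int, j: int) -> float:
        return 0.0 if j < i else self.W.get(i, j)

    def v(self, i: int, j: int) -> float:
        return FORBIDDEN if j <= i else self.V.get(i, j)

    def wm(self, i: int, j: int) -> float:
        return FORBIDDEN if j < i else self.WM.get(i, j)


def _interior_closings(i: int, j: int, cap: Optional[int]):
    """Yield (ip, jp) candidates for E3 in deterministic order."""
    for ip in range(i + 1, j - 1):
        left = ip - i - 1
        if cap is not None and left > cap:
            break
        for jp in range(j - 1, ip, -1):
            right = j - jp - 1
            if (ip - i) + (j - jp) <= 2:
                continue  # stack case, handled by E2
            if cap is not None and left + right > cap:
                break
            yield ip, jp


class ZukerStrategy(FoldStrategy):
    name = "zuker"
    aux_kind = "free_energy_op"

    def __init__(self, em: Optional[EnergyModel] = None):
        self.em = em or default_energy_model()

    def allocate(self, seq: RnaSequence, cfg: FoldConfig, audit: bool = False) -> ZukerState:
        return ZukerState(seq.n, self.em, audit=audit)

    def init(self, state: ZukerState, seq: RnaSequence, cfg: FoldConfig) -> None:
        pass

    def _v_candidates(
        self, state: ZukerState, i: int, j: int, seq: RnaSequence, cfg: FoldConfig
    ):
        """E1..E4 for a chemically pairable (i, j), in equation order."""
        em = state.em
        yield ("E1", None, em.hairpin(seq, i, j))
        inner = state.v(i + 1, j - 1)
        yield ("E2", None, em.stack(seq, i, j) + inner if math.isfinite(inner) else FORBIDDEN)
        for ip, jp in _interior_closings(i, j, cfg.interior_loop_cap):
            vin = state.V.get(ip, jp)
            if math.isfinite(vin):
                yield ("E3", (ip, jp), em.internal(seq, i, j, ip, jp) + vin)
        for k in range(i + 1, j - 1):
            left = state.WM.get(i + 1, k)
            right = state.WM.get(k + 1, j - 1)
            yield ("E4", k, em.multiloop_a + left + right)

    def fill_cell(
        self, state: ZukerState, i: int, j: int, seq: RnaSequence, cfg: FoldConfig
    ) -> None:
        if i == j:
            state.W.set(i, j, 0.0)
            state.V.set(i, j, FORBIDDEN)
            state.WM.set(i, j, FORBIDDEN)
            return
        em = state.em
        if j - i < cfg.min_span:
            state.V.set(i, j, FORBIDDEN)
            state.WM.set(i, j, FORBIDDEN)
            state.W.set(i, j, 0.0)
            return
        # V
        if can_pair(seq.base(i), seq.base(j), cfg.allowed_pairs):
            v_val = min(
                (e for _, _, e in self._v_candidates(state, i, j, seq, cfg)),
                default=FORBIDDEN,
            )
        else:
            v_val = FORBIDDEN
        state.V.set(i, j, v_val)
        # WM
        wm_val = min(
            state.wm(i, j - 1) + em.multiloop_c,
            state.wm(i + 1, j) + em.multiloop_c,
            v_val + em.multiloop_b,
        )
        for k in range(i, j):
            wm_val = min(wm_val, state.wm(i, k) + state.wm(k + 1, j))
        state.WM.set(i, j, wm_val)
        # W
        w_val = min(v_val, state.W.get(i + 1, j), state.W.get(i, j - 1))
        for k in range(i + 1, j - 1):
            w_val = min(w_val, state.W.get(i, k) + state.W.get(k + 1, j))
        state.W.set(i, j, w_val)

    def final_score(self, state: ZukerState) -> float:
        return state.W.get(1, state.n)

    def traceback(
        self, state: ZukerState, seq: RnaSequence, cfg: FoldConfig
    ) -> SecondaryStructure:
        pairs: List[BasePair] = []
        stack: List[Tuple[str, int, int]] = [("W", 1, state.n)]
        while stack:
            table, i, j = stack.pop()
            if j <= i:
                continue
            if table == "W":
                self._trace_w(state, i, j, seq, cfg, pairs, stack)
            elif table == "V":
                self._trace_v(state, i, j, seq, cfg, pairs, stack)
            else:
                self._trace_wm(state, i, j, seq, cfg, pairs, stack)
        return SecondaryStructure(n=state.n, pairs=frozenset(pairs))

    def _trace_w(self, state, i, j, seq, cfg, pairs, stack) -> None:
        if j - i < cfg.min_span:
            return  # only the empty structure fits
        target = state.W.get(i, j)
        v_val = state.V.get(i, j)
        if math.isfinite(v_val) and abs(v_val - target) <= _EPS:
            pairs.append(BasePair(i, j))
            stack.append(("V", i, j))
            return
        if abs(state.W.get(i + 1, j) - target) <= _EPS:
            stack.append(("W", i + 1, j))
            return
        if abs(state.W.get(i, j - 1) - target) <= _EPS:
            stack.append(("W", i, j - 1))
            return
        for k in range(i + 1, j - 1):
            if abs(state.W.get(i, k) + state.W.get(k + 1, j) - target) <= _EPS:
                stack.append(("W", k + 1, j))
                stack.append(("W", i, k))
                return
        raise AssertionError(f"no recurrence case reproduces W({i},{j})")

    def _trace_v(self, state, i, j, seq, cfg, pairs, stack) -> None:
        target = state.V.get(i, j)
        for case, arg, e in self._v_candidates(state, i, j, seq, cfg):
            if not math.isfinite(e) or abs(e - target) > _EPS:
                continue
            if case == "E1":
                return  # hairpin: nothing below
            if case == "E2":
                pairs.append(BasePair(i + 1, j - 1))
                stack.append(("V", i + 1, j - 1))
                return
            if case == "E3":
                ip, jp = arg
                pairs.append(BasePair(ip, jp))
                stack.append(("V", ip, jp))
                return
            k = arg
            stack.append(("WM", k + 1, j - 1))
            stack.append(("WM", i + 1, k))
            return
        raise AssertionError(f"no recurrence case reproduces V({i},{j})")

    def _trace_wm(self, state, i, j, seq, cfg, pairs, stack) -> None:
        em = state.em
        target = state.WM.get(i, j)
        cand = state.wm(i, j - 1) + em.multiloop_c
        if math.isfinite(cand) and abs(cand - target) <= _EPS:
            stack.append(("WM", i, j - 1))
            return
        cand = state.wm(i + 1, j) + em.multiloop_c
        if math.isfinite(cand) and abs(cand - target) <= _EPS:
            stack.append(("WM", i + 1, j))
            return
        v_val = state.V.get(i, j)
        if math.isfinite(v_val) and abs(v_val + em.multiloop_b - target) <= _EPS:
            pairs.append(BasePair(i, j))
            stack.append(("V", i, j))
            return
        for k in range(i, j):
            cand = state.wm(i, k) + state.wm(k + 1, j)
            if math.isfinite(cand) and abs(cand - target) <= _EPS:
                stack.append(("WM", k + 1, j))
                stack.append(("WM", i, k))
                return
        raise AssertionError(f"no recurrence case reproduces WM({i},{j})")

    def rescore(
        self, state: ZukerState, structure: SecondaryStructure, seq: RnaSequence, cfg: FoldConfig
    ) -> float:
        return loop_decomposition_energy(structure, seq, state.em)


# ---------------------------------------------------------------------------
# Loop decomposition (independent structure scoring; also the test oracle)
# ---------------------------------------------------------------------------


def _nesting_children(s: SecondaryStructure) -> Dict[Optional[BasePair], List[BasePair]]:
    """Map each pair (and the exterior, keyed None) to its directly nested pairs."""
    children: Dict[Optional[BasePair], List[BasePair]] = {None: []}
    stack: List[BasePair] = []
    for p in s.sorted_pairs():
        while stack and p.i > stack[-1].j:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children[p] = []
        stack.append(p)
    return children


def loop_decomposition_energy(
    s: SecondaryStructure, seq: RnaSequence, em: EnergyModel
) -> float:
    """Total energy of a valid nested structure, summed loop by loop.

    Each pair closes exactly one loop: a hairpin (no nested pairs), a stack
    or interior/bulge (one nested pair), or a multibranched loop (two or
    more), the latter costed as a + b * branches + c * unpaired.  Exterior
    bases are free.
    """
    children = _nesting_children(s)
    total = 0.0
    for p in s.pairs:
        cs = children[p]
        if not cs:
            total += em.hairpin(seq, p.i, p.j)
        elif len(cs) == 1:
            c = cs[0]
            if c.i == p.i + 1 and c.j == p.j - 1:
                total += em.stack(seq, p.i, p.j)
            else:
                total += em.internal(seq, p.i, p.j, c.i, c.j)
        else:
            unpaired = (p.j - p.i - 1) - sum(c.j - c.i + 1 for c in cs)
            total += em.multiloop_a + em.multiloop_b * len(cs) + em.multiloop_c * unpaired
    return total


def zuker_fill(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> ZukerState:
    cfg = cfg or FoldConfig()
    return engine.fill(seq, ZukerStrategy(em), cfg)


def zuker_traceback(
    state: ZukerState,
    seq: RnaSequence,
    cfg: Optional[FoldConfig] = None,
    em: Optional[EnergyModel] = None,
) -> SecondaryStructure:
    cfg = cfg or FoldConfig()
    return ZukerStrategy(em or state.em).traceback(state, seq, cfg)


def predict_zuker(
    seq: RnaSequence, cfg: Optional[FoldConfig] = None, em: Optional[EnergyModel] = None
) -> PredictionResult:
    cfg = cfg or FoldConfig()
    return engine.run(seq, ZukerStrategy(em), cfg)
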