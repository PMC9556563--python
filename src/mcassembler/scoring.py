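"""Multi-interface assembly scoring and the mpDockQ confidence score.

Each placed chain contributes ``avg_interface_plDDT * log10(n_interface_contacts)``,
with the interface taken over all of the chain's partners simultaneously (the
multiple-interface convention of DockQ). Summing the per-chain terms over the
complex gives the raw score ``x``, which a fitted sigmoid

    mpDockQ(x) = L / (1 + exp(-k (x - x0))) + b

maps to a DockQ-like accuracy estimate in (b, L+b). The default parameters
(L=0.728, x0=309.375, k=0.098, b=0.262) come from calibrating against
TM-scores of complexes assembled from trimeric subcomponents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .geometry import interface_contacts
from .structio import ChainStructure


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class MpDockQParams:
    L: float = 0.728
    x0: float = 309.375
    k: float = 0.098
    b: float = 0.262

    def __post_init__(self) -> None:
        if self.L <= 0 or self.k <= 0:
            raise ScoringError("sigmoid requires L > 0 and k > 0")


PAPER_PARAMS = MpDockQParams()


def chain_interface_term(chain: ChainStructure,
                         partners: Sequence[ChainStructure]) -> tuple[int, float, float]:
    """(n_contacts, avg interface plDDT, score term) for one chain.

    Contacts are pooled over all partners; the plDDT average runs over the
    chain's own residues that take part in at least one contact. A chain with
    zero contacts contributes 0 (log10 of zero contacts is undefined, and an
    unsupported chain should add no confidence).
    """
    contact_res: set[int] = set()
    n_contacts = 0
    for p in partners:
        if p is chain:
            continue
        pairs = interface_contacts(chain, p)
        n_contacts += len(pairs)
        contact_res.update(i for i, _ in pairs)
    if n_contacts == 0:
        return 0, 0.0, 0.0
    by_index = {r.index: r.plddt for r in chain.residues}
    avg_plddt = float(np.mean([by_index[i] for i in contact_res]))
    return n_contacts, avg_plddt, avg_plddt * math.log10(n_contacts)


def _chains_of(assembly) -> list[ChainStructure]:
    if hasattr(assembly, "placed"):
        return list(assembly.placed.values())
    return list(assembly)


def complex_score(assembly) -> float:
    """Sum of per-chain interface terms over all placed chains (the x of mpDockQ)."""
    chains = _chains_of(assembly)
    if not chains:
        raise ScoringError("cannot score an empty assembly")
    return float(sum(chain_interface_term(c, chains)[2] for c in chains))


def mpdockq(x: float, params: MpDockQParams = PAPER_PARAMS) -> float:
    """Sigmoid mapping the summed interface score to a DockQ-like value."""
    if not math.isfinite(x):
        raise ScoringError(f"score must be finite, got {x}")
    # guard exp overflow for very negative x; the limit is b
    z = -params.k * (x - params.x0)
    if z > 700:
        return params.b
    return params.L / (1.0 + math.exp(z)) + params.b


def fit_mpdockq(xs: Sequence[float], tms: Sequence[float],
                p0: MpDockQParams | None = None) -> tuple[MpDockQParams, float]:
    """Nonlinear least-squares fit of the sigmoid to (score, TM-like accuracy) pairs.

    Returns the fitted parameters and the residual norm. Constant accuracies
    give a degenerate fit and are rejected.
    """
    xs = np.asarray(xs, dtype=float)
    tms = np.asarray(tms, dtype=float)
    if xs.size < 4:
        raise ScoringError(f"need >= 4 points to fit 4 parameters, got {xs.size}")
    if np.allclose(xs, xs[0]):
        raise ScoringError("all scores identical; sigmoid fit is degenerate")
    if np.allclose(tms, tms[0]):
        raise ScoringError("all accuracies identical; sigmoid fit is degenerate")

    def f(x, L, x0, k, b):
        return L / (1.0 + np.exp(-np.clip(k * (x - x0), -700, 700))) + b

    if p0 is None:
        span = float(tms.max() - tms.min())
        guess = (max(span, 1e-3), float(np.median(xs)),
                 4.0 / max(float(xs.max() - xs.min()), 1e-6), float(tms.min()))
    else:
        guess = (p0.L, p0.x0, p0.k, p0.b)
    try:
        popt, _ = curve_fit(f, xs, tms, p0=guess, maxfev=20000)
    except RuntimeError as exc:
        raise ScoringError(f"sigmoid fit did not converge: {exc}") from exc
    params = MpDockQParams(*[float(v) for v in popt])
    resnorm = float(np.linalg.norm(f(xs, *popt) - tms))
    return params, resnorm


def roc_curve(labels: Sequence[int], scores: Sequence[float]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds) over the full threshold sweep.

    TPR = TP/(TP+FN) and FPR = FP/(FP+TN) at every distinct score threshold,
    predicting positive when score >= threshold; tied scores share a threshold.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ScoringError("labels and scores must have equal length")
    pos = int(labels.sum())
    neg = int(labels.size - pos)
    if pos == 0 or neg == 0:
        raise ScoringError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group ties: cumulative counts at the end of each tied block
    distinct = np.nonzero(np.r_[np.diff(s) != 0, True])[0]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / pos]
    fpr = np.r_[0.0, fp / neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(labels: Sequence[int], scores: Sequence[float]
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve plus area under it by trapezoidal integration."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def completeness(n_placed_or_assembly, stoichiometry: dict[str, int]) -> float:
    """Fraction of the stoichiometric chain count that has been placed."""
    total = sum(stoichiometry.values())
    if hasattr(n_placed_or_assembly, "placed"):
        placed = len(n_placed_or_assembly.placed)
    else:
        placed = int(n_placed_or_assembly)
    return placed / total


@dataclass
class ScoreReport:
    """Per-chain interface terms plus complex-level summary scores."""

    per_chain: dict[str, tuple[int, float, float]]
    total_score: float
    mpdockq: float
    completeness: float
    params: MpDockQParams = field(default_factory=MpDockQParams)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_chain": {
                k: {"n_interface_contacts": n, "avg_interface_plddt": p, "term": t}
                for k, (n, p, t) in self.per_chain.items()
            },
            "total_score": self.total_score,
            "mpdockq": self.mpdockq,
            "completeness": self.completeness,
            "mpdockq_params": asdict(self.params),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def score_report(chains: Iterable[ChainStructure],
                 stoichiometry: dict[str, int] | None = None,
                 params: MpDockQParams = PAPER_PARAMS,
                 labels: Sequence[str] | None = None) -> ScoreReport:
    """Full report for a set of placed chains."""
    chains = list(chains)
    if labels is None:
        labels = [c.chain_id for c in chains]
    per = {}
    total = 0.0
    for lab, c in zip(labels, chains):
        n, p, t = chain_interface_term(c, chains)
        per[lab] = (n, p, t)
        total += t
    comp = 1.0 if stoichiometry is None else completeness(len(chains), stoichiometry)
    return ScoreReport(per, total, mpdockq(total, params), comp, params)


def assembly_metrics(chains: Iterable[ChainStructure]) -> dict[str, float]:
    """Per-assembly separability metrics, normalised by the number of chains.

    These are the ROC candidate metrics: average interface plDDT, interface
    residues / contacts / interactions per chain, the summed
    plDDT*log10(contacts) score and its mpDockQ transform.
    """
    from .network import detect_interaction

    chains = list(chains)
    n_chains = len(chains)
    rep = score_report(chains)
    n_res = 0
    n_contacts = 0
    plddts = []
    for c in chains:
        nc, p, _ = rep.per_chain[c.chain_id]
        n_contacts += nc
        if nc:
            plddts.append(p)
        iface = set()
        for o in chains:
            if o is c:
                continue
            iface.update(i for i, _ in interface_contacts(c, o))
        n_res += len(iface)
    n_inter = sum(
        detect_interaction(a, b) for i, a in enumerate(chains) for b in chains[i + 1:]
    )
    return {
        "avg_interface_plddt": float(np.mean(plddts)) if plddts else 0.0,
        "interface_residues_per_chain": n_res / n_chains,
        "interface_contacts_per_chain": n_contacts / n_chains,
        "interactions_per_chain": n_inter / n_chains,
        "plddt_log_contacts": rep.total_score,
        "mpdockq": rep.mpdockq,
    }
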