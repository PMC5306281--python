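"""Pan-/core-/soft-core-genome growth simulation and saturation fits.

Accessions are merged in random order; a sequence of the newly added
accession is *novel* when no sequence already in the pool matches it at the
(deliberately permissive) novelty thresholds — identity >= 70% and coverage
>= 50% of the shorter sequence — so that retained introns and fragments do
not inflate the pan-genome.  The pan curve counts pool size per step, the
core curve the first accession's sequences matched by every accession seen so
far, and the soft-core relaxes "every" to about 95% of them.

Curves are fitted with the exponential-saturation (Tettelin-style) model
``y(n) = kappa * exp(-n / tau) + omega``: directly for the core curve, and on
the per-step novel-gene counts for the pan curve (whose fitted curve is then
rebuilt by cumulative summation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import curve_fit

from .matrices import soft_core_min_occupancy
from .pairwise import HSP, PairwiseHit, merge_all_pairs
from .seqio import AccessionSet


@dataclass
class GrowthCurve:
    """Permutation-sampled genome counts: one row per permutation."""

    kind: str  # pan | core | soft_core
    values: np.ndarray  # (permutations, n_genomes) ints
    seed: Optional[int]
    permutations: int

    @property
    def n_genomes(self) -> int:
        return self.values.shape[1]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "permutation\t" + "\t".join(f"n{i + 1}" for i in range(self.n_genomes)) + "\n"
            )
            for p in range(self.values.shape[0]):
                fh.write(f"{p + 1}\t" + "\t".join(str(v) for v in self.values[p]) + "\n")


@dataclass
class GrowthFit:
    """Exponential-saturation parameters for one curve."""

    model_name: str
    kappa: float
    tau: float
    omega: float
    residual_sse: float


def _match_adjacency(
    merged: dict[tuple[str, str], PairwiseHit],
    min_identity: float,
    min_coverage: float,
) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for (q, s), hit in merged.items():
        if hit.identity >= min_identity and hit.coverage >= min_coverage:
            adj.setdefault(q, set()).add(s)
            adj.setdefault(s, set()).add(q)
    return adj


def simulate_composition(
    seqs: AccessionSet,
    hits: Iterable[HSP] | dict[tuple[str, str], PairwiseHit],
    permutations: int = 20,
    novel_identity: float = 70.0,
    novel_coverage: float = 50.0,
    soft_fraction: float = 0.95,
    seed: Optional[int] = None,
) -> dict[str, GrowthCurve]:
    """Simulate pan/core/soft-core growth over random accession orderings.

    Within each permutation sequences are screened in order against the
    current pool (including same-step additions, which also removes
    within-accession redundancy at the novelty thresholds).  An accession
    "matches" a pool sequence when any of its sequences passes the novelty
    thresholds against it; the core at step n counts first-accession pool
    members matched by all n accessions seen so far.
    """
    if len(seqs.accessions) < 2:
        raise ValueError("growth simulation needs at least 2 accessions")
    merged = hits if isinstance(hits, dict) else merge_all_pairs(hits, seqs)
    adj = _match_adjacency(merged, novel_identity, novel_coverage)
    acc_of = {rec.seq_id: rec.accession for rec in seqs}
    ids_by_acc = {acc: sorted(r.seq_id for r in seqs.records[acc]) for acc in seqs.accessions}
    matched_accs = {
        sid: {acc_of[o] for o in adj.get(sid, ())} | {acc_of[sid]} for sid in acc_of
    }

    n_acc = len(seqs.accessions)
    rng = np.random.default_rng(seed)
    pan = np.zeros((permutations, n_acc), dtype=int)
    core = np.zeros((permutations, n_acc), dtype=int)
    soft = np.zeros((permutations, n_acc), dtype=int)

    for p in range(permutations):
        order = [seqs.accessions[i] for i in rng.permutation(n_acc)]
        pool: set[str] = set()
        first_pool: list[str] = []
        for n, acc in enumerate(order, start=1):
            for sid in ids_by_acc[acc]:
                if adj.get(sid, set()) & pool:
                    continue
                pool.add(sid)
                if n == 1:
                    first_pool.append(sid)
            seen = set(order[:n])
            pan[p, n - 1] = len(pool)
            core[p, n - 1] = sum(1 for sid in first_pool if seen <= matched_accs[sid])
            need = max(1, soft_core_min_occupancy(n, soft_fraction))
            soft[p, n - 1] = sum(
                1 for sid in pool if len(seen & matched_accs[sid]) >= need
            )

    return {
        "pan": GrowthCurve("pan", pan, seed, permutations),
        "core": GrowthCurve("core", core, seed, permutations),
        "soft_core": GrowthCurve("soft_core", soft, seed, permutations),
    }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _exp_decay(n, kappa, tau, omega):
    return kappa * np.exp(-n / tau) + omega


def _fit_points(n: np.ndarray, y: np.ndarray, n_max: int) -> GrowthFit:
    if np.allclose(y, y[0]):
        return GrowthFit("exp_decay", 0.0, 1.0, float(y[0]), 0.0)
    last = y[n == n.max()]
    omega_starts = [float(last.mean()), float(y[n >= max(n.max() - 2, n.min())].mean())]
    tau_starts = [1.0, max(n_max / 3.0, 0.5)]
    first = float(y[n == n.min()].mean())
    best: Optional[tuple[float, np.ndarray]] = None
    bounds = ([-np.inf, 1e-9, 0.0], [np.inf, np.inf, np.inf])
    for omega0 in omega_starts:
        for tau0 in tau_starts:
            p0 = [first - omega0, tau0, max(omega0, 0.0)]
            try:
                popt, _ = curve_fit(
                    _exp_decay, n, y, p0=p0, bounds=bounds, maxfev=20000
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(((y - _exp_decay(n, *popt)) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        warnings.warn("growth fit failed to converge from every start")
        return GrowthFit("exp_decay", 0.0, 1.0, float(y.mean()), float(((y - y.mean()) ** 2).sum()))
    sse, popt = best
    return GrowthFit("exp_decay", float(popt[0]), float(popt[1]), float(popt[2]), sse)


def fit_growth(curve: GrowthCurve, model: str = "exp_decay") -> GrowthFit:
    """Nonlinear least-squares saturation fit on all permutation points.

    Core-type curves are fitted directly; the pan curve is fitted on per-step
    novel-sequence counts (pan(n) - pan(n-1), n >= 2), whose asymptote
    ``omega`` is the number of novel genes contributed per additional genome.
    Multi-start initialization guards against the initialization sensitivity
    of exponential fits; the best-SSE start wins.
    """
    if model != "exp_decay":
        raise ValueError(f"unknown model {model!r}")
    values = curve.values
    n_genomes = curve.n_genomes
    if curve.kind == "pan":
        if n_genomes < 5:
            raise ValueError("pan fit needs at least 4 distinct per-step novel counts")
        novel = np.diff(values, axis=1)  # steps 2..N
        steps = np.arange(2, n_genomes + 1, dtype=float)
        n = np.tile(steps, values.shape[0])
        y = novel.reshape(-1).astype(float)
    else:
        if n_genomes < 4:
            raise ValueError("fit needs at least 4 distinct n values")
        steps = np.arange(1, n_genomes + 1, dtype=float)
        n = np.tile(steps, values.shape[0])
        y = values.reshape(-1).astype(float)
    return _fit_points(n, y, n_genomes)


def predicted_pan(curve: GrowthCurve, fit: GrowthFit) -> np.ndarray:
    """Fitted pan curve rebuilt by cumulative summation from mean pan(1)."""
    n = np.arange(2, curve.n_genomes + 1, dtype=float)
    novel = _exp_decay(n, fit.kappa, fit.tau, fit.omega)
    return np.concatenate(([curve.mean()[0]], curve.mean()[0] + np.cumsum(novel)))


@dataclass
class GrowthSummary:
    n_saturation: int
    coverage_target: float
    novel_per_genome: float
    core_asymptote: float
    final_pan_mean: float
    final_pan_sd: float


def growth_summary(
    curves: dict[str, GrowthCurve],
    fits: dict[str, GrowthFit],
    coverage_target: float = 0.99,
) -> GrowthSummary:
    """Saturation point and asymptotic rates from curves and fits.

    ``n_saturation`` is the smallest n whose mean pan size reaches
    ``coverage_target`` of the mean final pan size.
    """
    pan_mean = curves["pan"].mean()
    target = coverage_target * pan_mean[-1]
    n_star = int(np.argmax(pan_mean >= target) + 1)
    final = curves["pan"].values[:, -1].astype(float)
    return GrowthSummary(
        n_saturation=n_star,
        coverage_target=coverage_target,
        novel_per_genome=fits["pan"].omega if "pan" in fits else math.nan,
        core_asymptote=fits["core"].omega if "core" in fits else math.nan,
        final_pan_mean=float(final.mean()),
        final_pan_sd=float(final.std(ddof=1)) if len(final) > 1 else 0.0,
    )
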