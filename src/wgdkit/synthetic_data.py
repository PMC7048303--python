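"""Ground-truth data generators for every pipeline input.

Codon sequences evolve under a continuous-time mutation-selection process:
single-nucleotide codon changes occur at rate kappa (transitions) or 1
(transversions), multiplied by omega when the change is nonsynonymous, and
never into a stop codon.  Branch lengths are calibrated numerically, per
input codon composition, so that the *expected NG86-estimated* dS between
the output sequences equals the requested target (tolerance well under 1%);
this makes the generators directly comparable to the estimators they
exercise.  Expression matrices use negative-binomial counts around shared
or independent latent log-profiles; depth tracks are per-position Poisson
draws around a planted region layout.

Every generator is a pure function of its arguments including the seed, and
every generated dataset can serialize its ground truth ("SimTruth") as JSON
next to the data files, sufficient to score any downstream call.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import genetics
from .genetics import (
    CODON_INDEX,
    ND_MATRIX,
    N_SENSE,
    N_SITES,
    SD_MATRIX,
    SENSE_CODONS,
    S_SITES,
)
from .io_formats import DepthTrack, ExpressionMatrix, GeneRecord, SimilarityHit

__all__ = [
    "CodonProcess",
    "sim_ancestral_cds",
    "evolve_pair",
    "sim_pair_set",
    "sim_triple",
    "sim_expression",
    "sim_sex_contig",
    "score_regions",
    "write_truth",
    "read_truth",
]

#: expected-dS calibration tolerance (relative)
CALIBRATION_RTOL = 1e-4


# ---------------------------------------------------------------------------
# the codon substitution process


class CodonProcess:
    """K80-mutation x omega-acceptance codon substitution process.

    Rates between sense codons differing at one position: kappa for
    transitions, 1 for transversions, multiplied by omega when the amino
    acid changes; changes into stop codons have rate 0.  The process is
    cached per (omega, kappa) and exposes both simulation tables and an
    eigendecomposition-based transition matrix for expectations.
    """

    def __init__(self, omega: float, kappa: float):
        if omega < 0 or kappa <= 0:
            raise ValueError("require omega >= 0 and kappa > 0")
        self.omega = omega
        self.kappa = kappa
        Q = np.zeros((N_SENSE, N_SENSE))
        for i, a in enumerate(SENSE_CODONS):
            for pos in range(3):
                for b in genetics.BASES:
                    if b == a[pos]:
                        continue
                    c = a[:pos] + b + a[pos + 1 :]
                    if c in genetics.STOP_CODONS:
                        continue
                    rate = kappa if genetics.is_transition(a[pos], b) else 1.0
                    if genetics.AMINO_ACID[a] != genetics.AMINO_ACID[c]:
                        rate *= omega
                    Q[i, CODON_INDEX[c]] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.Q = Q
        # simulation tables: per codon, target indices and cumulative rates
        self.targets = []
        self.cum_rates = []
        self.total_rate = np.empty(N_SENSE)
        for i in range(N_SENSE):
            row = Q[i].copy()
            row[i] = 0.0
            nz = np.flatnonzero(row)
            self.targets.append(nz)
            self.cum_rates.append(np.cumsum(row[nz]))
            self.total_rate[i] = row[nz].sum()
        # eigendecomposition for fast P(t); verified against expm in tests
        vals, vecs = np.linalg.eig(Q)
        self._eval = vals
        self._evec = vecs
        self._evec_inv = np.linalg.inv(vecs)

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("t must be non-negative")
        P = (self._evec * np.exp(self._eval * t)) @ self._evec_inv
        P = np.maximum(P.real, 0.0)
        return P / P.sum(axis=1, keepdims=True)

    def evolve_codon(self, idx: int, t: float, rng: np.random.Generator) -> int:
        """Simulate the CTMC from codon index ``idx`` for time ``t``."""
        remaining = t
        while True:
            total = self.total_rate[idx]
            if total <= 0:
                return idx
            remaining -= rng.exponential(1.0 / total)
            if remaining < 0:
                return idx
            u = rng.random() * total
            k = int(np.searchsorted(self.cum_rates[idx], u, side="right"))
            k = min(k, len(self.targets[idx]) - 1)
            idx = int(self.targets[idx][k])


@lru_cache(maxsize=32)
def get_process(omega: float, kappa: float) -> CodonProcess:
    return CodonProcess(omega, kappa)


# ---------------------------------------------------------------------------
# expected NG86 estimates and branch-length calibration


def _expected_pair_counts(proc: CodonProcess, weights: np.ndarray, t_total: float):
    """Expected (sd, nd, S, N) between two tips at total divergence t_total.

    ``weights`` are ancestral sense-codon counts; both lineages evolve for
    t_total/2.  E[sd] per ancestor c is sum_ab P_ca P_cb SD_ab; expected
    site counts are the tip-marginal expectations (equal for both tips).
    """
    P = proc.transition_matrix(t_total / 2.0)
    esd = ((P @ SD_MATRIX) * P).sum(axis=1)
    end = ((P @ ND_MATRIX) * P).sum(axis=1)
    eS = P @ S_SITES
    eN = P @ N_SITES
    return (
        float(weights @ esd),
        float(weights @ end),
        float(weights @ eS),
        float(weights @ eN),
    )


def _expected_branch_counts(proc: CodonProcess, weights: np.ndarray, t: float):
    """Expected (sd, nd, S, N) between the ancestor and one tip at time t.

    Site counts are averaged between the (fixed) ancestor and the tip
    expectation, matching the pairwise NG86 convention.
    """
    P = proc.transition_matrix(t)
    esd = (P * SD_MATRIX).sum(axis=1)
    end = (P * ND_MATRIX).sum(axis=1)
    eS = 0.5 * (S_SITES + P @ S_SITES)
    eN = 0.5 * (N_SITES + P @ N_SITES)
    return (
        float(weights @ esd),
        float(weights @ end),
        float(weights @ eS),
        float(weights @ eN),
    )


def _jc(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0) if p < 0.75 else math.inf


def expected_ds(
    groups: Sequence[tuple[CodonProcess, np.ndarray]],
    t_total: float,
    mode: str = "pair",
) -> float:
    """Expected NG86+JC dS at divergence ``t_total``, over omega groups.

    ``groups`` pairs each process with the ancestral codon-count weights of
    the codons it governs (supporting per-window omega variation); counts
    are pooled before the JC correction, mirroring the estimator.
    """
    counter = _expected_pair_counts if mode == "pair" else _expected_branch_counts
    sd = S = 0.0
    for proc, weights in groups:
        s, _, ss, _ = counter(proc, weights, t_total)
        sd += s
        S += ss
    return _jc(sd / S)


def calibrate_time(
    groups: Sequence[tuple[CodonProcess, np.ndarray]],
    target_ds: float,
    mode: str = "pair",
) -> float:
    """Solve for the divergence time whose expected estimated dS hits target.

    Bisection (brentq) on the monotone map t -> expected dS.  Raises when
    the target exceeds what the process can reach before the Jukes-Cantor
    saturation boundary (impossible calibration).
    """
    if target_ds < 0:
        raise ValueError("target_ds must be non-negative")
    if target_ds == 0:
        return 0.0
    # grow an upper bracket while the expected dS stays finite and short of
    # the target; past the JC saturation boundary expected_ds returns inf
    t_lo, t_hi = 0.0, 0.5
    v = expected_ds(groups, t_hi, mode=mode)
    while math.isfinite(v) and v < target_ds:
        t_lo, t_hi = t_hi, t_hi * 2.0
        if t_hi > 1e4:
            raise ValueError(
                f"target dS {target_ds} is beyond saturation for this process "
                f"(plateau near {v:.3g})"
            )
        v = expected_ds(groups, t_hi, mode=mode)
    # shrink the upper bracket back inside the finite domain if needed
    for _ in range(200):
        if math.isfinite(v):
            break
        t_hi = 0.5 * (t_lo + t_hi)
        v = expected_ds(groups, t_hi, mode=mode)
    if not math.isfinite(v) or v < target_ds:
        raise ValueError(
            f"target dS {target_ds} is beyond saturation for this process "
            f"(max calibratable ~{v:.3g})"
        )
    f = lambda t: expected_ds(groups, t, mode=mode) - target_ds
    return float(brentq(f, t_lo, t_hi, xtol=1e-10, rtol=1e-12))


# ---------------------------------------------------------------------------
# sequence-level generators


def sim_ancestral_cds(n_codons: int, seed: int) -> str:
    """Random in-frame CDS: ATG followed by uniform random sense codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, N_SENSE, size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def _omega_of_codon(
    k: int, default_omega: float, omega_windows: Sequence[tuple[int, int, float]]
) -> float:
    for start, stop, om in omega_windows:
        if start <= k < stop:
            return om
    return default_omega


def _group_codons(
    anc_idx: np.ndarray,
    default_omega: float,
    kappa: float,
    omega_windows: Sequence[tuple[int, int, float]] | None,
):
    """Partition codon positions by omega; return [(proc, weights, positions)]."""
    omega_windows = omega_windows or []
    by_omega: dict[float, list[int]] = {}
    for k in range(len(anc_idx)):
        by_omega.setdefault(_omega_of_codon(k, default_omega, omega_windows), []).append(k)
    groups = []
    for om, positions in sorted(by_omega.items()):
        weights = np.bincount(anc_idx[positions], minlength=N_SENSE).astype(float)
        groups.append((get_process(om, kappa), weights, np.array(positions)))
    return groups


def _evolve_lineage(
    anc_idx: np.ndarray,
    groups,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = anc_idx.copy()
    for proc, _weights, positions in groups:
        for k in positions:
            out[k] = proc.evolve_codon(int(out[k]), t, rng)
    return out


def _indices_of(cds: str) -> np.ndarray:
    try:
        return np.array([CODON_INDEX[c] for c in genetics.codons_of(cds)], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"ancestral CDS contains a stop or invalid codon: {exc}")


def _to_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[int(i)] for i in idx)


def evolve_pair(
    ancestral: str,
    target_ds: float,
    omega: float,
    kappa: float,
    seed: int,
    omega_windows: Sequence[tuple[int, int, float]] | None = None,
) -> tuple[str, str, dict]:
    """Evolve two descendant CDS from a common ancestor.

    Total divergence time is calibrated so the expected NG86-estimated dS
    between the outputs equals ``target_ds``; each lineage runs for half.
    ``omega_windows`` is a list of (start_codon, stop_codon, omega) half-open
    overrides giving codon ranges a distinct omega (for window scans).
    Returns (cds_a, cds_b, truth).
    """
    anc_idx = _indices_of(ancestral)
    groups = _group_codons(anc_idx, omega, kappa, omega_windows)
    t_total = calibrate_time([(p, w) for p, w, _ in groups], target_ds, mode="pair")
    rng = np.random.default_rng(seed)
    a = _evolve_lineage(anc_idx, groups, t_total / 2.0, rng)
    b = _evolve_lineage(anc_idx, groups, t_total / 2.0, rng)
    truth = {
        "true_ds": target_ds,
        "omega": omega,
        "kappa": kappa,
        "omega_windows": [list(w) for w in (omega_windows or [])],
        "t_total": t_total,
        "n_codons": len(anc_idx),
    }
    return _to_cds(a), _to_cds(b), truth


def sim_triple(
    ancestral: str,
    branch_omegas: Mapping[str, float],
    target_ds_per_branch: Mapping[str, float],
    kappa: float,
    seed: int,
    branch_omega_windows: Mapping[str, Sequence[tuple[int, int, float]]] | None = None,
) -> tuple[dict[str, str], dict]:
    """Evolve an (ingroup1, ingroup2, outgroup) triple.

    The outgroup diverges first from the root; the ingroup ancestor then
    splits into the two ingroup lineages (an optional ``stem`` branch with
    its own omega/dS separates the two events; default length 0).  Each
    branch time is calibrated so the expected ancestor-to-tip NG86 dS equals
    its target.  Branch keys: outgroup, ingroup1, ingroup2[, stem].
    """
    required = {"outgroup", "ingroup1", "ingroup2"}
    if not required <= set(target_ds_per_branch):
        raise ValueError(f"target_ds_per_branch needs keys {sorted(required)}")
    windows = branch_omega_windows or {}
    anc_idx = _indices_of(ancestral)
    rng = np.random.default_rng(seed)

    def run_branch(start_idx: np.ndarray, branch: str) -> np.ndarray:
        ds = target_ds_per_branch.get(branch, 0.0)
        om = branch_omegas.get(branch, 1.0)
        grp = _group_codons(start_idx, om, kappa, windows.get(branch))
        t = calibrate_time([(p, w) for p, w, _ in grp], ds, mode="branch")
        return _evolve_lineage(start_idx, grp, t, rng)

    out_idx = run_branch(anc_idx, "outgroup")
    stem_idx = run_branch(anc_idx, "stem") if "stem" in target_ds_per_branch else anc_idx
    in1_idx = run_branch(stem_idx, "ingroup1")
    in2_idx = run_branch(stem_idx, "ingroup2")
    seqs = {
        "ingroup1": _to_cds(in1_idx),
        "ingroup2": _to_cds(in2_idx),
        "outgroup": _to_cds(out_idx),
    }
    truth = {
        "branch_omegas": dict(branch_omegas),
        "target_ds_per_branch": dict(target_ds_per_branch),
        "branch_omega_windows": {k: [list(w) for w in v] for k, v in windows.items()},
        "kappa": kappa,
        "n_codons": len(anc_idx),
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# WGD-burst pair sets


def sim_pair_set(
    n_wgd: int,
    n_ssd: int,
    burst_ds_mean: float = 0.69,
    burst_ds_sd: float = 0.08,
    ssd_ds_mean: float = 0.15,
    omega_dist: float | Callable[[np.random.Generator], float] = 0.2,
    n_codons: int = 300,
    kappa: float = 2.0,
    seed: int = 0,
) -> tuple[list[GeneRecord], list[SimilarityHit], dict]:
    """A WGD burst plus small-scale-duplication background pair set.

    WGD pairs draw true dS from a lognormal with median ``burst_ds_mean``
    and log-sd ``burst_ds_sd``; SSD pairs draw from an exponential with mean
    ``ssd_ds_mean``.  Per-pair omega comes from ``omega_dist`` (a constant
    or a callable of the rng).  Emits gene records, a synthetic hit table
    with one hit per pair (round-trips through the pair catalog to exactly
    the planted pairs), and per-pair truth.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    hits: list[SimilarityHit] = []
    truth: dict[str, dict] = {}
    draw_omega = omega_dist if callable(omega_dist) else (lambda _rng: float(omega_dist))
    specs = [("wgd", i, float(rng.lognormal(math.log(burst_ds_mean), burst_ds_sd)))
             for i in range(n_wgd)]
    specs += [("ssd", i, float(rng.exponential(ssd_ds_mean))) for i in range(n_ssd)]
    for kind, i, ds in specs:
        base = f"{kind}{i:05d}"
        ga, gb = f"{base}a", f"{base}b"
        omega = draw_omega(rng)
        anc = sim_ancestral_cds(n_codons, int(rng.integers(2**31)))
        cds_a, cds_b, pair_truth = evolve_pair(
            anc, ds, omega, kappa, int(rng.integers(2**31))
        )
        genes.append(GeneRecord(gene_id=ga, cds=cds_a))
        genes.append(GeneRecord(gene_id=gb, cds=cds_b))
        hits.append(SimilarityHit(ga, gb, 1e-180, 1000.0))
        truth[f"{ga}--{gb}"] = {**pair_truth, "origin": kind}
    return genes, hits, truth


# ---------------------------------------------------------------------------
# expression matrices


def sim_expression(
    n_pairs: int,
    frac_divergent: float,
    n_stages: int = 8,
    seed: int = 0,
    n_bias_pairs: int = 0,
    bias_odds: float = 1.0,
    mean_depth: float = 300.0,
    dispersion: float = 0.1,
    profile_sd: float = 1.0,
) -> tuple[ExpressionMatrix, list[tuple[str, str]], dict]:
    """Paired expression counts over n_stages x {M, F} samples.

    Conserved pairs share one latent log-profile (per-sample N(0,
    ``profile_sd``) deviations); the default amplitude is calibrated so the
    count-scale correlation of conserved paralogs targets r^2 ~ 0.8 given
    negative-binomial noise at dispersion 0.1.  Divergent pairs draw
    independent profiles (expected sample r^2 ~ 1/(n_samples-1) ~ 0.07).  The planted number of divergent pairs is
    round(frac_divergent * n_pairs).  The first ``n_bias_pairs`` pairs also
    multiply paralog-a male-sample means by ``bias_odds``.  Returns the
    count matrix, the pair list, and per-pair truth.
    """
    if not 0 <= frac_divergent <= 1:
        raise ValueError("frac_divergent must be in [0, 1]")
    rng = np.random.default_rng(seed)
    stages = [f"st{i + 1}" for i in range(n_stages)]
    sexes = ["M", "F"]
    samples = [(st, sx) for st in stages for sx in sexes]
    n_samples = len(samples)
    male_mask = np.array([sx == "M" for _, sx in samples])

    n_divergent = int(round(frac_divergent * n_pairs))
    divergent = np.zeros(n_pairs, dtype=bool)
    divergent[rng.choice(n_pairs, size=n_divergent, replace=False)] = True

    nb_n = 1.0 / dispersion  # NB shape: var = mu + dispersion * mu^2
    gene_ids: list[str] = []
    pair_list: list[tuple[str, str]] = []
    counts = np.zeros((2 * n_pairs, n_samples), dtype=np.int64)
    truth: dict[str, dict] = {}
    for i in range(n_pairs):
        ga, gb = f"exp{i:05d}a", f"exp{i:05d}b"
        base_a = mean_depth * math.exp(rng.normal(0.0, 0.5))
        base_b = mean_depth * math.exp(rng.normal(0.0, 0.5))
        prof_a = rng.normal(0.0, profile_sd, size=n_samples)
        prof_b = prof_a if not divergent[i] else rng.normal(0.0, profile_sd, size=n_samples)
        mu_a = base_a * np.exp(prof_a)
        mu_b = base_b * np.exp(prof_b)
        biased = i < n_bias_pairs
        if biased:
            mu_a = np.where(male_mask, mu_a * bias_odds, mu_a)
        counts[2 * i] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_a))
        counts[2 * i + 1] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_b))
        gene_ids += [ga, gb]
        pair_list.append((ga, gb))
        truth[f"{ga}--{gb}"] = {
            "divergent": bool(divergent[i]),
            "bias_odds": bias_odds if biased else 1.0,
        }

    sample_ids = [f"{st}_{sx}" for st, sx in samples]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids, dtype=float),
        sex=pd.Series([sx for _, sx in samples], index=sample_ids),
        stage=pd.Series([st for st, _ in samples], index=sample_ids),
        unit="counts",
    )
    meta = {
        "pairs": truth,
        "n_divergent": int(n_divergent),
        "stages": stages,
        "profile_sd": profile_sd,
        "dispersion": dispersion,
    }
    return matrix, pair_list, meta


# ---------------------------------------------------------------------------
# sex-contig depth tracks

_CLASS_LAMBDAS = {
    # class -> (male multiplier, female multiplier) of the single-copy depth
    "male-specific": (1.0, 0.0),
    "PAR-like": (1.0, 1.0),
    "background": (1.0, 1.0),
    "repetitive": (4.0, 4.0),
}


def sim_sex_contig(
    length_bp: int,
    layout: Sequence[tuple[tuple[int, int], str]],
    expected_depth: float = 20.0,
    seed: int = 0,
    noiseless: bool = False,
    contig: str = "chrY",
) -> tuple[DepthTrack, dict]:
    """Male/female depth track with a planted region layout.

    ``layout`` lists ((start, end), class) half-open intervals; positions not
    covered default to ``background`` (single-copy depth in both sexes).
    Per-position depths are Poisson around the class lambdas (male-specific:
    (d, 0); PAR-like and background: (d, d); repetitive: (4d, 4d)), or the
    rounded lambdas exactly when ``noiseless``.
    """
    lam_m = np.full(length_bp, expected_depth)
    lam_f = np.full(length_bp, expected_depth)
    for (start, end), cls in layout:
        if cls not in _CLASS_LAMBDAS:
            raise ValueError(f"unknown region class {cls!r}")
        if not 0 <= start < end <= length_bp:
            raise ValueError(f"interval ({start}, {end}) outside contig")
        fm, ff = _CLASS_LAMBDAS[cls]
        lam_m[start:end] = fm * expected_depth
        lam_f[start:end] = ff * expected_depth
    if noiseless:
        male = np.round(lam_m).astype(np.int64)
        female = np.round(lam_f).astype(np.int64)
    else:
        rng = np.random.default_rng(seed)
        male = rng.poisson(lam_m)
        female = rng.poisson(lam_f)
    truth = {
        "length_bp": length_bp,
        "layout": [[list(iv), cls] for iv, cls in layout],
        "expected_depth": expected_depth,
        "noiseless": noiseless,
        "contig": contig,
    }
    return DepthTrack(contig, male, female), truth


def score_regions(calls, truth: dict) -> dict:
    """Base-level confusion of region calls against a planted layout.

    Bases whose truth class is ``background`` are scored as PAR-like (both
    share the single-copy, both-sexes depth signature).  Returns the
    confusion matrix {truth_class: {called_class: n_bases}} and overall
    accuracy over the planted (non-background) classes.
    """
    length = truth["length_bp"]
    true_cls = np.full(length, "PAR-like", dtype=object)
    for (start, end), cls in [(tuple(iv), c) for iv, c in truth["layout"]]:
        true_cls[start:end] = "PAR-like" if cls == "background" else cls
    called = np.full(length, "uncalled", dtype=object)
    for c in calls:
        called[c.start : c.end] = c.call
    confusion: dict[str, dict[str, int]] = {}
    correct = 0
    for t, c in zip(true_cls, called):
        confusion.setdefault(t, {}).setdefault(c, 0)
        confusion[t][c] += 1
        correct += t == c
    return {"confusion": confusion, "accuracy": correct / length}


# ---------------------------------------------------------------------------
# SimTruth sidecars


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialize a ground-truth dict as pretty JSON (the SimTruth sidecar)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
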