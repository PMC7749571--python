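"""End-to-end validation experiments on synthetic ground truth.

These are the package's own calibration and recovery studies, run by the
test suite and by ``scripts/acceptance.py``.  Problem sizes are desk-scale
defaults (tens of channels, hundreds of Hz, tens of replicates) chosen so
each experiment completes in seconds to a few minutes; every size is a
keyword argument.

Experiments
-----------
* :func:`null_edge_retention` — on i.i.d. channels (no band filtering, so
  the raw sample count is the true one) the uncorrected per-edge retention
  rate at alpha should equal alpha.
* :func:`planted_recovery` — sensitivity and per-edge false-positive rate of
  edge detection on band-limited data with planted r=0.5 couplings, using
  the effective-sample-size threshold (band filtering leaves far fewer
  effective samples than raw ones; see the connectivity module notes).
* :func:`cohort_recovery` — full pipeline power study: replicate cohorts
  with a planted beta-band clustering deficit and an FSIQ coupling; reports
  how often the deficit survives FDR and the score-metric correlation has
  the right sign, plus the corresponding null-cohort rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import (
    WeightedGraph,
    critical_r,
    fc_matrix,
    threshold_graph,
    threshold_graph_effective,
)
from .graph_metrics import metrics_record
from .group_analysis import correlate, run_group_comparison
from .io_core import AnalysisConfig, CohortTable, band_by_name
from .preprocessing import CleanWindow, band_filter, preprocess_subject
from .synthetic_data import (
    GroundTruth,
    default_cohort_truth,
    make_ground_truth,
    null_cohort_truth,
    simulate_cohort,
    simulate_subject,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def null_edge_retention(
    seed: int,
    n_channels: int = 30,
    K: int = 2000,
    n_rep: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Uncorrected edge-retention rate on independent white-noise channels."""
    retained = 0
    total = 0
    for s in _child_seeds(seed, n_rep):
        rng = np.random.default_rng(s)
        X = rng.standard_normal((n_channels, K))
        window = CleanWindow(
            subject_id="null", group="control", fs=float(K), start=0, stop=K,
            channel_labels=tuple(f"ch{i:03d}" for i in range(n_channels)),
            data=X, band_data={"broadband": X},
        )
        g = threshold_graph(fc_matrix(window, "broadband"), alpha=alpha)
        n_pairs = n_channels * (n_channels - 1) // 2
        retained += g.n_edges
        total += n_pairs
    return {"rate": retained / total, "n": total}


# ---------------------------------------------------------------------------
# planted-edge recovery
# ---------------------------------------------------------------------------

def planted_recovery(
    seed: int,
    n_seeds: int = 50,
    n_channels: int = 20,
    fs: float = 300.0,
    duration_s: float = 60.0,
    band: str = "beta",
    r: float = 0.5,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity / false-positive rate of planted-edge detection.

    Modules of 3 coupled channels (channels beyond the last full module stay
    uncoupled) at target correlation ``r``; detection uses the effective-
    sample-size threshold, appropriate for band-limited data.
    """
    truth = make_ground_truth(
        n_channels=n_channels, bands=(band,), module_size=3, r=r,
    )
    planted = {(e.i, e.j) for e in truth.edges}
    bdef = band_by_name(band)
    hits = misses = fps = tns = 0
    r_sum = 0.0
    r_n = 0
    for s in _child_seeds(seed, n_seeds):
        ts = simulate_subject(
            truth, "control", fs, duration_s, s, heterogeneity=False
        )
        filt = band_filter(ts.data, bdef, fs)
        window = CleanWindow(
            subject_id=ts.subject_id, group=ts.group, fs=fs, start=0,
            stop=ts.n_samples, channel_labels=ts.channel_labels,
            data=ts.data, band_data={band: filt},
        )
        g = threshold_graph_effective(window, band, alpha=alpha)
        cm = fc_matrix(window, band)
        for i in range(n_channels):
            for j in range(i + 1, n_channels):
                retained = g.W[i, j] != 0
                if (i, j) in planted:
                    r_sum += cm.R[i, j]
                    r_n += 1
                    hits += retained
                    misses += not retained
                else:
                    fps += retained
                    tns += not retained
    return {
        "sensitivity": hits / max(hits + misses, 1),
        "fpr": fps / max(fps + tns, 1),
        "mean_planted_R": r_sum / max(r_n, 1),
        "n_planted": hits + misses,
        "n_null": fps + tns,
    }


# ---------------------------------------------------------------------------
# cohort-level recovery
# ---------------------------------------------------------------------------

def _analyze_cohort(
    recordings, cohort: CohortTable, config: AnalysisConfig
) -> CohortTable:
    """simulate -> preprocess -> connect -> metrics, in memory."""
    rows = []
    for ts in recordings:
        window = preprocess_subject(ts, config)
        for bname in window.band_data:
            g = threshold_graph(fc_matrix(window, bname), alpha=config.alpha)
            rec = metrics_record(g)
            rows.append({"subject_id": ts.subject_id, "band": bname,
                         **rec.scalars()})
    return CohortTable(subjects=cohort.subjects, metrics=pd.DataFrame(rows))


def cohort_recovery(
    seed: int,
    n_cohorts: int = 50,
    planted: bool = True,
    n_patient: int = 22,
    n_control: int = 18,
    n_channels: int = 9,
    fs: float = 300.0,
    duration_s: float = 20.0,
    bands: tuple[str, ...] = ("theta", "alpha", "beta"),
    effect_band: str = "beta",
    alpha: float = 0.05,
) -> dict:
    """Replicate-cohort power / null-calibration study for the full pipeline.

    For each replicate: simulate the cohort, run screening + band
    decomposition + thresholded connectivity + graph metrics, compare groups
    on CA per band with FDR across the band family, and (planted cohorts)
    correlate FSIQ with the recovered effect-band CA within the patient
    group.

    Returns per-replicate success rates:
      detection_rate   — effect-band CA FDR-significant with patient < control
      spearman_sign_rate — FSIQ~CA Spearman positive (planted runs)
      joint_rate       — both at once (planted runs)
      significant_comparison_rate — significant fraction of all (replicate ×
                          band) CA comparisons (the null calibration figure)
      null_abs_rho_lt_03_rate — cohort-wide |Spearman| < 0.3 (null runs)
    """
    band_defs = tuple(band_by_name(b) for b in bands)
    config = AnalysisConfig(
        bands=band_defs, fs=fs, window_s=duration_s, alpha=alpha,
        artifact_amp_pT=6.0, notch_hz=50.0,
    )
    detect = 0
    sign_ok = 0
    joint = 0
    n_sig_comparisons = 0
    n_comparisons = 0
    null_rho_small = 0
    for s in _child_seeds(seed, n_cohorts):
        truth = (
            default_cohort_truth(n_channels=n_channels, bands=bands,
                                 removal_band=effect_band, seed=s)
            if planted
            else null_cohort_truth(n_channels=n_channels, bands=bands, seed=s)
        )
        recordings, cohort, _ = simulate_cohort(
            truth, n_patient=n_patient, n_control=n_control,
            fs=fs, duration_s=duration_s, seed=s,
        )
        cohort = _analyze_cohort(recordings, cohort, config)
        stats = run_group_comparison(
            cohort, score_vars=(), metric_vars=("CA",), alpha=alpha
        )
        ca = stats[stats["comparison"] == "CA"]
        n_comparisons += len(ca)
        n_sig_comparisons += int(ca["significant"].sum())

        m = cohort.metrics
        pat_ids = set(cohort.group_ids("patient"))
        sel = m[m["band"] == effect_band]
        ca_pat = sel[sel["subject_id"].isin(pat_ids)]["CA"].to_numpy()
        ca_ctl = sel[~sel["subject_id"].isin(pat_ids)]["CA"].to_numpy()
        row = ca[ca["band"] == effect_band]
        detected = bool(row["significant"].iloc[0]) and (
            np.nanmean(ca_pat) < np.nanmean(ca_ctl)
        )
        detect += detected

        subj = cohort.subjects.set_index("subject_id")
        pat_order = [i for i in sel["subject_id"] if i in pat_ids]
        fsiq = subj.loc[pat_order, "FSIQ"].to_numpy(dtype=float)
        ca_vals = sel.set_index("subject_id").loc[pat_order, "CA"].to_numpy(dtype=float)
        ok = np.isfinite(fsiq) & np.isfinite(ca_vals)
        if ok.sum() >= 4 and fsiq[ok].std() > 0 and ca_vals[ok].std() > 0:
            rho = correlate(fsiq[ok], ca_vals[ok], "spearman").statistic
        else:
            rho = 0.0
        if planted:
            sign_ok += rho > 0
            joint += detected and rho > 0
        else:
            # cohort-wide score-metric correlation under the null
            allsel = sel.set_index("subject_id")
            order = [i for i in allsel.index]
            x = subj.loc[order, "FSIQ"].to_numpy(dtype=float)
            y = allsel.loc[order, "CA"].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            rho_all = correlate(x[ok], y[ok], "spearman").statistic
            null_rho_small += abs(rho_all) < 0.3
    out = {
        "detection_rate": detect / n_cohorts,
        "significant_comparison_rate": n_sig_comparisons / max(n_comparisons, 1),
        "n_cohorts": n_cohorts,
        "n_comparisons": n_comparisons,
    }
    if planted:
        out["spearman_sign_rate"] = sign_ok / n_cohorts
        out["joint_rate"] = joint / n_cohorts
    else:
        out["null_abs_rho_lt_03_rate"] = null_rho_small / n_cohorts
    return out


# ---------------------------------------------------------------------------
# graph-metric oracle checks (pure-python independent implementations)
# ---------------------------------------------------------------------------

def brute_strength(W: np.ndarray):
    n = W.shape[0]
    S = [sum(abs(W[i][j]) for j in range(n) if j != i) for i in range(n)]
    return np.array(S), sum(S) / n


def brute_degree(W: np.ndarray):
    n = W.shape[0]
    d = [sum(1 for j in range(n) if j != i and W[i][j] != 0) for i in range(n)]
    return np.array(d, dtype=float), sum(d) / n


def brute_paths_enumeration(W: np.ndarray) -> np.ndarray:
    """Shortest paths by exhaustive simple-path enumeration (tiny graphs)."""
    n = W.shape[0]
    A = np.abs(W)
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def extend(path, length):
        i = path[-1]
        for j in range(n):
            if A[i][j] > 0 and j not in path:
                new_len = length + 1.0 / A[i][j]
                if new_len < best[path[0]][j]:
                    best[path[0]][j] = new_len
                extend(path + [j], new_len)

    for start in range(n):
        extend([start], 0.0)
    return best


def brute_floyd_warshall(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    A = np.abs(W)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and A[i][j] > 0:
                D[i][j] = 1.0 / A[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return D


def brute_la(L: np.ndarray) -> float:
    n = L.shape[0]
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(L[i][j]) and L[i][j] > 0:
                s += 1.0 / L[i][j]
    s /= n * (n - 1)
    return 1.0 / s if s > 0 else float("inf")


def brute_clustering(W: np.ndarray):
    """Direct triple summation of the geometric-mean clustering."""
    n = W.shape[0]
    A = np.abs(np.asarray(W, dtype=float))
    wmax = A.max()
    H = A / wmax if wmax > 0 else A
    C = np.zeros(n)
    for i in range(n):
        d = sum(1 for j in range(n) if j != i and A[i][j] > 0)
        if d < 2:
            continue
        tot = 0.0
        for j in range(n):
            for k in range(n):
                if j != i and k != i and j != k:
                    tot += (H[i][j] * H[j][k] * H[k][i]) ** (1.0 / 3.0)
        C[i] = tot / (d * (d - 1))
    return C, C.mean()


def _connected(W: np.ndarray) -> bool:
    n = W.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(n):
            if W[i][j] != 0 and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def _all_connected_topologies(n: int):
    """All connected labeled graphs on n nodes (edge subsets of K_n)."""
    import itertools

    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(1, 2 ** len(pairs)):
        A = np.zeros((n, n))
        for b, (i, j) in enumerate(pairs):
            if bits >> b & 1:
                A[i, j] = A[j, i] = 1.0
        if _connected(A):
            yield A


def graph_metric_oracle_check(
    seed: int,
    max_exhaustive_nodes: int = 5,
    n_random: int = 100,
    random_nodes: tuple[int, int] = (8, 12),
) -> dict:
    """Maximum |implementation - brute force| over an enumeration of small
    connected weighted graphs plus random mid-size graphs.

    Exhaustive simple-path enumeration serves as the shortest-path oracle on
    the enumerated graphs; Floyd-Warshall (an algorithm independent of the
    implementation's Dijkstra) covers the random graphs, where path
    enumeration is combinatorially infeasible.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    n_graphs = 0

    def check(W, enumerate_paths: bool):
        nonlocal max_err, n_graphs
        g = WeightedGraph(
            nodes=tuple(f"n{i}" for i in range(W.shape[0])),
            W=np.asarray(W, dtype=float), K=3, band="test",
            subject_id="oracle", alpha=1.0, tp_crit=0.0,
        )
        rec = metrics_record(g)
        S, SA = brute_strength(W)
        d, DA = brute_degree(W)
        L = brute_paths_enumeration(W) if enumerate_paths else brute_floyd_warshall(W)
        LA = brute_la(L)
        C, CA = brute_clustering(W)
        finite = np.isfinite(rec.L) & np.isfinite(L)
        errs = [
            np.max(np.abs(rec.S - S)), abs(rec.SA - SA),
            np.max(np.abs(rec.d - d)), abs(rec.DA - DA),
            np.max(np.abs(rec.L[finite] - L[finite])),
            0.0 if (np.isinf(rec.LA) and np.isinf(LA)) else abs(rec.LA - LA),
            np.max(np.abs(rec.C - C)), abs(rec.CA - CA),
        ]
        if not (np.isinf(rec.L) == np.isinf(L)).all():
            errs.append(np.inf)
        max_err = max(max_err, float(np.max(errs)))
        n_graphs += 1

    for n in range(2, max_exhaustive_nodes + 1):
        for A in _all_connected_topologies(n):
            W = A * rng.uniform(0.1, 1.0, size=A.shape)
            W = (W + W.T) / 2 * (A > 0)
            check(W, enumerate_paths=True)

    lo, hi = random_nodes
    for _ in range(n_random):
        n = int(rng.integers(lo, hi + 1))
        A = (rng.uniform(size=(n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        W = A * rng.uniform(0.05, 1.0, size=(n, n))
        W = np.triu(W, 1)
        W = W + W.T
        check(W, enumerate_paths=False)

    return {"max_abs_error": max_err, "n_graphs": n_graphs}
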