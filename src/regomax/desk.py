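"""Canned desk-scale verification suite.

Recomputes, from scratch and without any external download, the checks that
validate the pipeline end-to-end: the fixture overlap percentages, the
reduced-matrix method contract on random networks, planted hidden-link
recovery, and the finite-difference sensitivity consistency.  Returns a
report with measured values, expectations and pass flags; used by the
``reproduce-desk`` CLI command and by the repository's acceptance script.
"""

from __future__ import annotations

import time

import numpy as np

from .graph_core import DirectedNetwork, build_google_matrix
from .ranking import pagerank
from .rank_compare import load_fixture, overlap_curve
from .reduced_matrix import component_weights, reduce
from .sensitivity import perturb_column, sensitivity
from .synthetic_data import default_config, generate, planted_recovery_config

__all__ = ["run_desk_suite", "fixture_overlaps", "regomax_contract_battery",
           "planted_recovery_battery", "sensitivity_scheme_check", "random_network"]


def fixture_overlaps() -> dict:
    """Top-j overlaps between the encyclopedia cancer PageRank order and the
    epidemiology rankings (GBD-2017 deaths, GLOBOCAN-2018 deaths/new cases)."""
    wiki = load_fixture("wikipedia_cancers")
    gbd = load_fixture("gbd2017_deaths")
    glob_d = load_fixture("globocan2018_deaths")
    glob_n = load_fixture("globocan2018_newcases")
    eta10_gbd = overlap_curve(wiki, gbd, j_max=10).at(10)
    eta10_glob = overlap_curve(wiki, glob_d, j_max=10).at(10)
    eta5_new = overlap_curve(wiki, glob_n, j_max=5).at(5)
    return {
        "eta10_gbd_deaths": eta10_gbd,
        "eta10_globocan_deaths": eta10_glob,
        "eta5_globocan_newcases": eta5_new,
        "pct10_gbd_deaths": 10.0 * eta10_gbd,
        "pct10_globocan_deaths": 10.0 * eta10_glob,
        "pct5_globocan_newcases": 20.0 * eta5_new,
    }


def random_network(rng: np.random.Generator, n_min: int = 5, n_max: int = 60,
                   p: float = 0.15) -> DirectedNetwork:
    """Directed Erdos-Renyi network with at least one link."""
    n = int(rng.integers(n_min, n_max + 1))
    ids = [f"n{i}" for i in range(n)]
    while True:
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        if mask.any():
            break
    links = {(ids[i], ids[j]) for i, j in zip(*np.nonzero(mask))}
    return DirectedNetwork(ids, links)


def regomax_contract_battery(seed: int, n_networks: int = 200) -> dict:
    """Check the reduced-matrix contract on random networks (N <= 60,
    N_r <= 12): spectral/direct agreement, PageRank conservation, weight-sum
    identity.  Returns the worst-case errors."""
    max_method_err = 0.0
    max_pagerank_err = 0.0
    max_weight_err = 0.0
    for i in range(n_networks):
        rng = np.random.default_rng([seed, i])
        net = random_network(rng)
        G = build_google_matrix(net)
        n_r = int(rng.integers(1, min(12, net.N - 1) + 1))
        subset = [net.node_ids[k] for k in rng.choice(net.N, size=n_r, replace=False)]
        direct = reduce(G, subset, method="direct")
        spectral = reduce(G, subset, method="spectral")
        max_method_err = max(max_method_err, float(np.max(np.abs(direct.G_R - spectral.G_R))))
        p_global = pagerank(G).probabilities
        idx = [net.index_of(x) for x in subset]
        p_restricted = p_global[idx] / p_global[idx].sum()
        max_pagerank_err = max(
            max_pagerank_err, float(np.max(np.abs(direct.pagerank() - p_restricted)))
        )
        w = component_weights(direct)
        max_weight_err = max(max_weight_err, abs(w["W_rr"] + w["W_pr"] + w["W_qr"] - 1.0))
    return {
        "n_networks": n_networks,
        "max_method_disagreement": max_method_err,
        "max_pagerank_consistency_error": max_pagerank_err,
        "max_weight_sum_error": max_weight_err,
    }


def planted_recovery_battery(seed: int, n_runs: int = 50) -> dict:
    """Over seeded synthetic configs with one planted two-hop pathway, count
    how often the planted pair is the off-diagonal argmax of G_qrnd."""
    hits = 0
    for i in range(n_runs):
        cfg = planted_recovery_config(seed=seed * 1009 + i)
        net, cats = generate(cfg)
        G = build_google_matrix(net)
        subset = sorted(n for n, c in cats.items() if c == "entity")
        rgm = reduce(G, subset, method="spectral")
        q = rgm.G_qrnd
        i_max, j_max = np.unravel_index(np.argmax(q), q.shape)
        src_plant, _, tgt_plant = cfg.planted_paths[0]
        if subset[j_max] == src_plant and subset[i_max] == tgt_plant:
            hits += 1
    return {"n_runs": n_runs, "recovered": hits}


def sensitivity_scheme_check(seed: int, n_instances: int = 8) -> dict:
    """Central-difference sensitivities at delta = 1e-3 and 1e-4 must agree
    to three significant digits; a delta = 0 perturbation must be an exact
    identity."""
    max_rel = 0.0
    max_identity = 0.0
    for i in range(n_instances):
        cfg = default_config(seed=seed * 7919 + i)
        net, cats = generate(cfg)
        G = build_google_matrix(net)
        subset = sorted(n for n, c in cats.items() if c in ("cancer", "drug"))[:10]
        rgm = reduce(G, subset, method="spectral")
        rng = np.random.default_rng([seed, i])
        b, a = rng.choice(len(subset), size=2, replace=False)
        src, tgt = subset[b], subset[a]
        d3 = sensitivity(rgm, src, tgt, delta=1e-3)
        d4 = sensitivity(rgm, src, tgt, delta=1e-4)
        max_rel = max(max_rel, abs(d3 - d4) / max(abs(d3), abs(d4)))
        M0 = perturb_column(rgm.G_R, int(a), int(b), 0.0)
        max_identity = max(max_identity, float(np.max(np.abs(M0 - rgm.G_R))))
    return {
        "n_instances": n_instances,
        "max_scheme_relative_difference": max_rel,
        "max_zero_delta_change": max_identity,
    }


def run_desk_suite(seed: int = 1, n_regomax: int = 200, n_recovery: int = 50) -> dict:
    """Run the full desk-scale suite and assemble a pass/fail report."""
    t0 = time.time()
    report: dict = {"seed": seed, "checks": {}}

    ov = fixture_overlaps()
    report["checks"]["fixture_overlaps"] = {
        "measured": ov,
        "expected": {"eta10_gbd_deaths": 7, "eta10_globocan_deaths": 6,
                     "eta5_globocan_newcases": 4},
        "passed": ov["eta10_gbd_deaths"] == 7 and ov["eta10_globocan_deaths"] == 6
        and ov["eta5_globocan_newcases"] == 4,
    }

    contract = regomax_contract_battery(seed, n_networks=n_regomax)
    report["checks"]["regomax_contract"] = {
        "measured": contract,
        "expected": {"max_method_disagreement": "< 1e-10",
                     "max_pagerank_consistency_error": "< 1e-9",
                     "max_weight_sum_error": "< 1e-9"},
        "passed": contract["max_method_disagreement"] < 1e-10
        and contract["max_pagerank_consistency_error"] < 1e-9
        and contract["max_weight_sum_error"] < 1e-9,
    }

    recovery = planted_recovery_battery(seed, n_runs=n_recovery)
    report["checks"]["hidden_link_recovery"] = {
        "measured": recovery,
        "expected": {"recovered": f">= {int(0.9 * n_recovery)} of {n_recovery}"},
        "passed": recovery["recovered"] >= int(0.9 * n_recovery),
    }

    schemes = sensitivity_scheme_check(seed)
    report["checks"]["sensitivity_schemes"] = {
        "measured": schemes,
        "expected": {"max_scheme_relative_difference": "< 5e-4 (3 significant digits)",
                     "max_zero_delta_change": "< 1e-14"},
        "passed": schemes["max_scheme_relative_difference"] < 5e-4
        and schemes["max_zero_delta_change"] < 1e-14,
    }

    report["all_passed"] = all(c["passed"] for c in report["checks"].values())
    report["elapsed_seconds"] = round(time.time() - t0, 2)
    return report
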