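"""Seeded drivers that regenerate the package's quantitative results.

Each ``run_*`` function sweeps a parameter grid, averages over independent
realizations, and returns a tidy :class:`pandas.DataFrame` (optionally also
written to CSV):

- :func:`run_divergence` — neutral-evolution divergence trajectories D(T)
  versus rescaled time, for several population sizes / string lengths.
- :func:`run_giant_richness` — largest-component fraction and richness
  versus ``mu/mu_c``, with the analytic giant-component and richness curves.
- :func:`run_clustering` — empirical versus exact mean clustering across
  the threshold range.
- :func:`run_assortativity` — degree assortativity versus G/B with an
  Erdos-Renyi comparator at matched mean degree.
- :func:`run_geodesic` — mean geodesic distance versus G/B (and mu/mu_c)
  with a matched Erdos-Renyi comparator.

Realizations are reproducible bit-for-bit: the RNG for every (grid point,
replicate) is derived from the master seed through a ``SeedSequence`` key,
so any single grid point can be regenerated in isolation.

Default grids and realization counts are desk-scale study conditions
(N = 1024 networks, 50 realizations; 100-bit strings for the geodesic
sweep); every driver takes overrides for quicker smoke runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics, theory
from .bitstrings import random_distinct_set
from .evolution import run_evolution
from .network import network_from_distances, pairwise_distances

__all__ = [
    "realization_rng",
    "run_divergence",
    "plateau_divergence",
    "run_giant_richness",
    "run_clustering",
    "run_assortativity",
    "run_geodesic",
    "default_geodesic_grid",
    "run_experiment",
    "plot_experiment",
    "EXPERIMENTS",
]

# stable integer tags so per-point seeds never collide across experiments
_TAGS = {"fig2": 2, "fig34": 3, "fig5": 5, "fig6": 6, "fig7": 7, "er": 90}


def realization_rng(master_seed: int, tag: str | int, *key: int) -> np.random.Generator:
    """Deterministic per-(experiment, grid point, replicate) generator."""
    tag = _TAGS.get(tag, tag) if isinstance(tag, str) else tag
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), tag, *map(int, key))))


def _maybe_write(df: pd.DataFrame, out: str | Path | None) -> pd.DataFrame:
    if out is not None:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out, index=False)
    return df


# ---------------------------------------------------------------------------
# Neutral evolution (divergence trajectories)
# ---------------------------------------------------------------------------


def run_divergence(
    cases: Sequence[tuple[int, int]] = ((256, 20), (512, 20), (1024, 20)),
    n_units: float = 6.0,
    record_units: float = 0.1,
    reps: int = 50,
    variant: str = "random-death",
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Realization-averaged divergence trajectories D(T) for several (N, B).

    ``n_units`` is the run length and ``record_units`` the recording cadence,
    both in rescaled time T/(N*B).  Columns: N, B, step, rescaled_time,
    D_mean, D_sd.
    """
    frames = []
    for N, B in cases:
        total = int(round(n_units * N * B))
        every = max(1, int(round(record_units * N * B)))
        trajs = []
        steps = None
        for rep in range(reps):
            rng = realization_rng(seed, "fig2", N, B, rep)
            df = run_evolution(N, B, total, record_every=every, variant=variant, rng=rng)
            trajs.append(df["D"].to_numpy())
            steps = df["step"].to_numpy()
        arr = np.array(trajs)
        frames.append(
            pd.DataFrame(
                {
                    "N": N,
                    "B": B,
                    "step": steps,
                    "rescaled_time": steps / (N * B),
                    "D_mean": arr.mean(axis=0),
                    "D_sd": arr.std(axis=0, ddof=1) if reps > 1 else 0.0,
                }
            )
        )
    return _maybe_write(pd.concat(frames, ignore_index=True), out)


def plateau_divergence(df: pd.DataFrame, tail_fraction: float = 0.2) -> pd.DataFrame:
    """Plateau estimate per (N, B): the mean of D_mean over the final
    ``tail_fraction`` of recorded points."""
    rows = []
    for (N, B), grp in df.groupby(["N", "B"]):
        grp = grp.sort_values("step")
        n_tail = max(1, int(round(tail_fraction * len(grp))))
        rows.append({"N": N, "B": B, "D_plateau": grp["D_mean"].tail(n_tail).mean()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold sweeps over network realizations
# ---------------------------------------------------------------------------


def _sweep(N, B, G_values, reps, seed, tag, measure):
    """Generate ``reps`` random distinct sets, build the network for every G
    from one cached distance matrix per realization, and apply ``measure``.

    ``measure(adj, G) -> dict``; returns {G: list of dicts over reps}.
    """
    G_values = list(G_values)
    results: dict[int, list[dict]] = {G: [] for G in G_values}
    for rep in range(reps):
        rng = realization_rng(seed, tag, B, rep)
        strings = random_distinct_set(N, B, rng)
        dist = pairwise_distances(strings)
        for G in G_values:
            adj = dist <= G
            np.fill_diagonal(adj, False)
            results[G].append(measure(adj, G))
    return results


def _nanstats(values: Iterable[float | None]) -> tuple[float, float, int]:
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    n = int(np.sum(~np.isnan(arr)))
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(np.nanmean(arr))
    sd = float(np.nanstd(arr, ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def run_giant_richness(
    N: int = 1024,
    B: int = 20,
    G_values: Sequence[int] | None = None,
    reps: int = 50,
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Largest-component fraction and richness versus the threshold G.

    Attaches the analytic columns: ``S_theory`` (finite-N generating-
    function solution), ``S_theory_largeN`` (large-N form, a function of
    mu/mu_c only) and ``R_approx`` (isolated-plus-dyad richness estimate).
    """
    G_values = range(1, B + 1) if G_values is None else G_values

    def measure(adj, G):
        comps = metrics.components(adj)
        return {"S": len(comps[0]) / N, "R": len(comps) / N}

    res = _sweep(N, B, G_values, reps, seed, "fig34", measure)
    mc = theory.mu_critical(N)
    rows = []
    for G, recs in res.items():
        m = theory.mu(B, G)
        s_mean, s_sd, _ = _nanstats(r["S"] for r in recs)
        r_mean, r_sd, _ = _nanstats(r["R"] for r in recs)
        rows.append(
            {
                "N": N,
                "B": B,
                "G": G,
                "mu": m,
                "ratio": m / mc,
                "S_mean": s_mean,
                "S_sd": s_sd,
                "R_mean": r_mean,
                "R_sd": r_sd,
                "S_theory": theory.solve_giant(m, N)[1],
                "S_theory_largeN": theory.solve_giant_largeN(m / mc)[1],
                "R_approx": theory.richness_approx(m / mc),
            }
        )
    return _maybe_write(pd.DataFrame(rows), out)


def run_clustering(
    N: int = 1024,
    Bs: Sequence[int] = (20,),
    G_values: Sequence[int] | None = None,
    reps: int = 50,
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Empirical mean clustering versus G/B, with the exact combinatorial
    prediction in column ``C_theory``."""
    frames = []
    for B in Bs:
        gs = range(1, B + 1) if G_values is None else G_values

        def measure(adj, G):
            return {"C": metrics.mean_clustering(adj)}

        res = _sweep(N, B, gs, reps, seed, "fig5", measure)
        for G, recs in res.items():
            c_mean, c_sd, n_def = _nanstats(r["C"] for r in recs)
            frames.append(
                {
                    "N": N,
                    "B": B,
                    "G": G,
                    "G_over_B": G / B,
                    "C_mean": c_mean,
                    "C_sd": c_sd,
                    "n_defined": n_def,
                    "C_theory": theory.clustering_C(B, G),
                }
            )
    return _maybe_write(pd.DataFrame(frames), out)


def run_assortativity(
    N: int = 1024,
    Bs: Sequence[int] = (20, 30, 50),
    reps: int = 50,
    seed: int = 0,
    er_match_B: int | None = 30,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Degree assortativity versus G/B for each string length.

    For ``B == er_match_B`` an Erdos-Renyi comparator with the same number
    of links (``round(mu N(N-1)/2)``) is generated per realization and its
    assortativity reported in the ``A_er_*`` columns.
    """
    frames = []
    for B in Bs:
        gs = range(1, B + 1)

        def measure(adj, G):
            return {"A": metrics.assortativity(adj)}

        res = _sweep(N, B, gs, reps, seed, "fig6", measure)
        for G, recs in res.items():
            a_mean, a_sd, n_def = _nanstats(r["A"] for r in recs)
            row = {
                "N": N,
                "B": B,
                "G": G,
                "G_over_B": G / B,
                "A_mean": a_mean,
                "A_sd": a_sd,
                "n_defined": n_def,
                "A_er_mean": float("nan"),
                "A_er_sd": float("nan"),
                "n_er_defined": 0,
            }
            if B == er_match_B:
                m_links = round(theory.mu(B, G) * N * (N - 1) / 2)
                ers = []
                for rep in range(reps):
                    rng = realization_rng(seed, "er", B, G, rep)
                    ers.append(metrics.assortativity(metrics.er_graph(N, m_links, rng)))
                row["A_er_mean"], row["A_er_sd"], row["n_er_defined"] = _nanstats(ers)
            frames.append(row)
    return _maybe_write(pd.DataFrame(frames), out)


def default_geodesic_grid(B: int = 100, N: int = 1024) -> list[int]:
    """Threshold grid for the geodesic sweep: every G whose mu/mu_c falls
    in [0.005, 8] (the sparse limit through the percolation transition)
    plus sparse points out to G = B so both flat ends of the curve are
    probed."""
    mc = theory.mu_critical(N)
    grid = [G for G in range(1, B + 1) if 0.005 <= theory.mu(B, G) / mc <= 8.0]
    hi = [G for G in (B // 2, 3 * B // 4, B) if G > (grid[-1] if grid else 0)]
    return grid + sorted(set(hi))


def run_geodesic(
    N: int = 1024,
    B: int = 100,
    G_values: Sequence[int] | None = None,
    reps: int = 50,
    seed: int = 0,
    er: bool = True,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Mean geodesic distance versus G/B and mu/mu_c, with a matched
    Erdos-Renyi comparator (same N, same link count)."""
    if G_values is None:
        G_values = default_geodesic_grid(B, N)

    def measure(adj, G):
        return {"L": metrics.mean_geodesic(adj)}

    res = _sweep(N, B, G_values, reps, seed, "fig7", measure)
    mc = theory.mu_critical(N)
    rows = []
    for G, recs in res.items():
        m = theory.mu(B, G)
        l_mean, l_sd, n_def = _nanstats(r["L"] for r in recs)
        row = {
            "N": N,
            "B": B,
            "G": G,
            "G_over_B": G / B,
            "mu": m,
            "ratio": m / mc,
            "L_mean": l_mean,
            "L_sd": l_sd,
            "n_defined": n_def,
            "L_er_mean": float("nan"),
            "L_er_sd": float("nan"),
        }
        if er:
            m_links = round(m * N * (N - 1) / 2)
            ers = []
            for rep in range(reps):
                rng = realization_rng(seed, "er", B, G, rep + 1000)
                ers.append(metrics.mean_geodesic(metrics.er_graph(N, m_links, rng)))
            row["L_er_mean"], row["L_er_sd"], _ = _nanstats(ers)
        rows.append(row)
    return _maybe_write(pd.DataFrame(rows), out)


# ---------------------------------------------------------------------------
# Dispatch and plotting
# ---------------------------------------------------------------------------

EXPERIMENTS = {
    "fig2": run_divergence,
    "fig3": run_giant_richness,
    "fig4": run_giant_richness,
    "fig5": run_clustering,
    "fig6": run_assortativity,
    "fig7": run_geodesic,
}


def run_experiment(name: str, **kwargs) -> pd.DataFrame:
    """Run a named experiment (fig2..fig7) with keyword overrides."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    return EXPERIMENTS[name](**kwargs)


def plot_experiment(name: str, df: pd.DataFrame, path: str | Path) -> None:
    """Quick-look plot of an experiment's output (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if name == "fig2":
        for (N, B), grp in df.groupby(["N", "B"]):
            ax.semilogy(grp["rescaled_time"], grp["D_mean"], label=f"N={N}, B={B}")
        ax.set_xlabel("T / (N B)")
        ax.set_ylabel("D")
    elif name in ("fig3", "fig4"):
        emp, th = ("S_mean", "S_theory_largeN") if name == "fig3" else ("R_mean", "R_approx")
        sd = "S_sd" if name == "fig3" else "R_sd"
        grp = df.sort_values("ratio")
        ax.errorbar(grp["ratio"], grp[emp], yerr=grp[sd], fmt="o", label="simulation")
        ax.plot(grp["ratio"], grp[th], "-", label="theory")
        ax.set_xlabel("mu / mu_c")
        ax.set_ylabel("S" if name == "fig3" else "R")
    elif name == "fig5":
        for B, grp in df.groupby("B"):
            grp = grp.sort_values("G_over_B")
            ax.plot(grp["G_over_B"], grp["C_mean"], "o", label=f"B={B} (sim)")
            ax.plot(grp["G_over_B"], grp["C_theory"], "-", label=f"B={B} (theory)")
        ax.set_xlabel("G / B")
        ax.set_ylabel("C")
    elif name == "fig6":
        for B, grp in df.groupby("B"):
            grp = grp.sort_values("G_over_B")
            ax.errorbar(grp["G_over_B"], grp["A_mean"], yerr=grp["A_sd"], fmt="o-", label=f"B={B}")
            if grp["n_er_defined"].sum() > 0:
                ax.plot(grp["G_over_B"], grp["A_er_mean"], "--", label=f"ER (B={B} match)")
        ax.set_xlabel("G / B")
        ax.set_ylabel("A")
    elif name == "fig7":
        grp = df.sort_values("G_over_B")
        ax.errorbar(grp["G_over_B"], grp["L_mean"], yerr=grp["L_sd"], fmt="o-", label="similarity")
        ax.plot(grp["G_over_B"], grp["L_er_mean"], "--", label="ER")
        ax.set_xlabel("G / B")
        ax.set_ylabel("L")
    ax.legend(fontsize=8)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
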