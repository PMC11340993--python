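"""Ensemble runs over the (p_proximity x p_wave) rule-probability grid.

For every grid cell, ``R`` independently seeded random digraphs are evolved
for ``M`` iterations and their final topology is measured.  Besides the
global measures (modularity, average efficiency, connectedness), the sweep
tracks the fate of the designated wave-initiator nodes — do they become
divergent hubs, and divergent hubs of convergent-divergent units? — against
a matched control of randomly drawn non-initiator nodes, and the fate of the
nodes they target (the out-neighbours of initiators in the final network),
which in the biological reading correspond to amacrine-like cells gaining
input and losing output.

Replicates are keyed by ``(cell index, replicate index)`` through
independent seed sequences derived from one master seed, so results are
reproducible and invariant to execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph_core import RewiringConfig, SpatialDigraph, init_random_digraph
from .network_metrics import (
    average_efficiency,
    classify_hubs,
    connected_pairs,
    find_cdus,
    modularity,
)
from .rewiring_engine import evolve

__all__ = [
    "ReplicateRecord",
    "SweepResult",
    "run_replicate",
    "run_ensemble",
    "initiator_statistics",
    "targeted_statistics",
    "cdu_statistics",
    "plot_heatmaps",
]

logger = logging.getLogger(__name__)

#: Number of random non-initiator draws behind the control proportions.
N_CONTROL_DRAWS = 1000


def _derived_seed(master_seed: int, *key: int) -> int:
    """Deterministic, order-invariant seed for a (cell, replicate) job."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ReplicateRecord:
    """Final-state measurements of one evolved network."""

    p_proximity: float
    p_wave: float
    replicate: int
    seed: int
    initiators: tuple[int, ...]
    n: int
    in_degrees: np.ndarray
    out_degrees: np.ndarray
    Q: float
    E_avg: float
    connected_pairs: int
    convergent_hubs: frozenset[int]
    divergent_hubs: frozenset[int]
    #: (convergent, divergent, size, density-or-None) per unit
    cdus: tuple[tuple[int, int, int, float | None], ...]
    targeted: frozenset[int]
    #: nodes targeted by an initiator out-link at any point during the run
    targeted_ever: frozenset[int] = frozenset()

    @property
    def connected_fraction(self) -> float:
        return self.connected_pairs / self.n**2

    @property
    def cdu_divergent_hubs(self) -> frozenset[int]:
        return frozenset(d for _, d, _, _ in self.cdus)

    @property
    def cdu_convergent_hubs(self) -> frozenset[int]:
        return frozenset(c for c, _, _, _ in self.cdus)


def run_replicate(config: RewiringConfig) -> ReplicateRecord:
    """Initialise, evolve and measure one network from ``config.seed``."""
    rng = config.rng()
    cfg = config.with_initiators(config.resolve_initiators())
    G = init_random_digraph(cfg, rng)
    inits = set(cfg.initiators or ())
    ever: set[int] = {
        int(u) for c in inits for u in G.out_neighbors(c)
    }
    G, events = evolve(G, cfg, rng)
    ever.update(e.added[1] for e in events if e.added[0] in inits)
    return measure_final(G, cfg, targeted_ever=frozenset(ever))


def measure_final(
    G: SpatialDigraph,
    config: RewiringConfig,
    targeted_ever: frozenset[int] | None = None,
) -> ReplicateRecord:
    """Measure an already-evolved graph under its configuration."""
    conv, div = classify_hubs(G, config.hub_threshold)
    cdus = find_cdus(G, config.hub_threshold)
    initiators = config.initiators or ()
    targeted: set[int] = set()
    for c in initiators:
        targeted.update(int(u) for u in G.out_neighbors(c))
    Q, _ = modularity(G)
    return ReplicateRecord(
        p_proximity=config.p_proximity,
        p_wave=config.p_wave,
        replicate=0,
        seed=config.seed,
        initiators=tuple(initiators),
        n=G.n,
        in_degrees=G.in_degrees().astype(int),
        out_degrees=G.out_degrees().astype(int),
        Q=Q,
        E_avg=average_efficiency(G),
        connected_pairs=connected_pairs(G),
        convergent_hubs=frozenset(int(v) for v in conv),
        divergent_hubs=frozenset(int(v) for v in div),
        cdus=tuple((u.convergent, u.divergent, u.size, u.density) for u in cdus),
        targeted=frozenset(targeted),
        targeted_ever=(
            frozenset(targeted) if targeted_ever is None else targeted_ever
        ),
    )


# ---------------------------------------------------------------------------
# per-cell statistics


def initiator_statistics(
    records: list[ReplicateRecord],
    rng: np.random.Generator,
    n_draws: int = N_CONTROL_DRAWS,
) -> dict[str, float]:
    """Initiator-versus-rest connectivity and hub-formation statistics.

    Means are taken over pooled nodes across replicates.  The control
    proportions repeat the initiator questions on ``n_draws`` uniform
    (replicate, non-initiator node) picks, mirroring the random selection
    used for the non-initiator baselines.
    """
    init_out, init_in, rest_out, rest_in = [], [], [], []
    init_div, init_cdu_div = [], []
    for r in records:
        inits = np.array(r.initiators, dtype=int)
        others = np.setdiff1d(np.arange(r.n), inits)
        init_out.extend(r.out_degrees[inits])
        init_in.extend(r.in_degrees[inits])
        rest_out.extend(r.out_degrees[others])
        rest_in.extend(r.in_degrees[others])
        init_div.extend(int(i in r.divergent_hubs) for i in inits)
        init_cdu_div.extend(int(i in r.cdu_divergent_hubs) for i in inits)
    out = {
        "initiator_out_degree": float(np.mean(init_out)),
        "initiator_in_degree": float(np.mean(init_in)),
        "noninitiator_out_degree": float(np.mean(rest_out)),
        "noninitiator_in_degree": float(np.mean(rest_in)),
        "initiator_divergent_hub_prop": float(np.mean(init_div)),
        "initiator_cdu_divergent_hub_prop": float(np.mean(init_cdu_div)),
    }
    out["out_degree_ratio"] = _ratio(
        out["initiator_out_degree"], out["noninitiator_out_degree"]
    )
    out["in_degree_ratio"] = _ratio(
        out["initiator_in_degree"], out["noninitiator_in_degree"]
    )
    # control: random non-initiator nodes pooled across replicates
    hits_div = hits_cdu = 0
    for _ in range(n_draws):
        r = records[rng.integers(len(records))]
        others = np.setdiff1d(np.arange(r.n), np.array(r.initiators, dtype=int))
        v = int(others[rng.integers(others.size)])
        hits_div += v in r.divergent_hubs
        hits_cdu += v in r.cdu_divergent_hubs
    out["control_divergent_hub_prop"] = hits_div / n_draws
    out["control_cdu_divergent_hub_prop"] = hits_cdu / n_draws
    return out


def targeted_statistics(
    records: list[ReplicateRecord], scope: str = "final"
) -> dict[str, float]:
    """Connectivity of nodes targeted by initiator out-links vs the rest.

    With ``scope="final"`` (default) the targeted set is read off the final
    network; ``scope="ever"`` uses every node targeted at any point of the
    run.  Non-targeted excludes the initiators themselves.  Replicates
    whose targeted set is empty are excluded from targeted means (counted
    in ``targeted_empty_replicates``).
    """
    if scope not in ("final", "ever"):
        raise ValueError(f"scope must be 'final' or 'ever', got {scope!r}")
    t_out, t_in, nt_out, nt_in = [], [], [], []
    t_conv, nt_conv, t_cdu_conv, nt_cdu_conv = [], [], [], []
    empty = 0
    for r in records:
        pool = r.targeted if scope == "final" else r.targeted_ever
        targeted = np.array(sorted(pool), dtype=int)
        if targeted.size == 0:
            empty += 1
            logger.warning(
                "replicate %d: initiator(s) %s have no final out-links",
                r.replicate, r.initiators,
            )
        excluded = set(pool) | set(r.initiators)
        rest = np.array([v for v in range(r.n) if v not in excluded], dtype=int)
        t_out.extend(r.out_degrees[targeted])
        t_in.extend(r.in_degrees[targeted])
        nt_out.extend(r.out_degrees[rest])
        nt_in.extend(r.in_degrees[rest])
        t_conv.extend(int(v in r.convergent_hubs) for v in targeted)
        nt_conv.extend(int(v in r.convergent_hubs) for v in rest)
        t_cdu_conv.extend(int(v in r.cdu_convergent_hubs) for v in targeted)
        nt_cdu_conv.extend(int(v in r.cdu_convergent_hubs) for v in rest)
    t_out_arr = np.array(t_out, dtype=float)
    t_in_arr = np.array(t_in, dtype=float)
    out = {
        "targeted_out_degree": float(np.mean(t_out_arr)) if t_out else np.nan,
        "targeted_in_degree": float(np.mean(t_in_arr)) if t_in else np.nan,
        "nontargeted_out_degree": float(np.mean(nt_out)),
        "nontargeted_in_degree": float(np.mean(nt_in)),
        "targeted_zero_out_prop": float(np.mean(t_out_arr == 0)) if t_out else np.nan,
        "targeted_zero_in_prop": float(np.mean(t_in_arr == 0)) if t_in else np.nan,
        "nontargeted_zero_out_prop": float(np.mean(np.array(nt_out) == 0)),
        "nontargeted_zero_in_prop": float(np.mean(np.array(nt_in) == 0)),
        "targeted_convergent_hub_prop": float(np.mean(t_conv)) if t_conv else np.nan,
        "nontargeted_convergent_hub_prop": float(np.mean(nt_conv)),
        "targeted_cdu_convergent_hub_prop": (
            float(np.mean(t_cdu_conv)) if t_cdu_conv else np.nan
        ),
        "nontargeted_cdu_convergent_hub_prop": float(np.mean(nt_cdu_conv)),
        "targeted_empty_replicates": float(empty),
    }
    out["targeted_out_degree_ratio"] = _ratio(
        out["targeted_out_degree"], out["nontargeted_out_degree"]
    )
    out["targeted_in_degree_ratio"] = _ratio(
        out["targeted_in_degree"], out["nontargeted_in_degree"]
    )
    return out


def cdu_statistics(records: list[ReplicateRecord]) -> dict[str, float]:
    """Counts of convergent-divergent units and their intermediate subgraphs.

    Size and density are averaged over units whose intermediate subgraph has
    more than one node, split by whether the unit's divergent hub is a wave
    initiator.
    """
    counts = [len(r.cdus) for r in records]
    sizes_i, dens_i, sizes_o, dens_o = [], [], [], []
    conv_prop, div_prop = [], []
    for r in records:
        conv_prop.append(len(r.convergent_hubs) / r.n)
        div_prop.append(len(r.divergent_hubs) / r.n)
        for _, d, size, density in r.cdus:
            if size <= 1:
                continue
            if d in r.initiators:
                sizes_i.append(size)
                dens_i.append(density)
            else:
                sizes_o.append(size)
                dens_o.append(density)
    return {
        "convergent_hub_prop": float(np.mean(conv_prop)),
        "divergent_hub_prop": float(np.mean(div_prop)),
        "cdu_count": float(np.mean(counts)),
        "cdu_success_prop": float(np.mean([c > 0 for c in counts])),
        "cdu_size_initiator_hub": float(np.mean(sizes_i)) if sizes_i else np.nan,
        "cdu_density_initiator_hub": float(np.mean(dens_i)) if dens_i else np.nan,
        "cdu_size_other_hub": float(np.mean(sizes_o)) if sizes_o else np.nan,
        "cdu_density_other_hub": float(np.mean(dens_o)) if dens_o else np.nan,
    }


def _ratio(a: float, b: float) -> float:
    return float(a / b) if b else np.nan


def _sem(x: list[float]) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


# ---------------------------------------------------------------------------
# the sweep


@dataclass
class SweepResult:
    """Per-cell ensemble averages over replicate networks.

    ``cells`` has one row per grid cell with all per-cell statistics;
    ``records`` keeps the replicate-level measurements for dispersion
    estimates and reanalysis.
    """

    p_proximity_values: list[float]
    p_wave_values: list[float]
    R: int
    master_seed: int
    cells: pd.DataFrame
    records: list[ReplicateRecord] = field(default_factory=list, repr=False)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (cell, statistic)."""
        keep = [c for c in self.cells.columns if c not in ("p_proximity", "p_wave")]
        tidy = self.cells.melt(
            id_vars=["p_proximity", "p_wave"],
            value_vars=keep,
            var_name="statistic",
            value_name="value",
        )
        tidy["R"] = self.R
        return tidy


def validate_grid(
    p_proximity_values: list[float], p_wave_values: list[float]
) -> list[tuple[float, float]]:
    """All grid cells; rejects cells whose probabilities exceed one."""
    cells = []
    for pp in p_proximity_values:
        for pw in p_wave_values:
            if pp + pw > 1 + 1e-12:
                raise ValueError(
                    f"invalid grid cell (p_proximity={pp}, p_wave={pw}): "
                    "p_proximity + p_wave > 1"
                )
            cells.append((float(pp), float(pw)))
    return cells


def run_ensemble(
    base_config: RewiringConfig,
    p_proximity_values: list[float],
    p_wave_values: list[float],
    R: int,
    master_seed: int = 0,
) -> SweepResult:
    """Evolve ``R`` replicate networks in every grid cell and average.

    Every replicate runs from its own seed derived from ``master_seed`` and
    the (cell, replicate) key, so the result is independent of execution
    order and bit-reproducible.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    cells = validate_grid(p_proximity_values, p_wave_values)
    rows = []
    all_records: list[ReplicateRecord] = []
    for ci, (pp, pw) in enumerate(cells):
        cfg_cell = replace(
            base_config,
            p_proximity=pp,
            p_wave=pw,
            p_adaptive=1.0 - pp - pw,
        )
        recs = []
        for rep in range(R):
            cfg = replace(cfg_cell, seed=_derived_seed(master_seed, ci, rep))
            rec = replace(run_replicate(cfg), replicate=rep)
            recs.append(rec)
        logger.info("cell %d/%d (p_proximity=%.2f, p_wave=%.2f) done",
                    ci + 1, len(cells), pp, pw)
        ctrl_rng = np.random.default_rng(_derived_seed(master_seed, ci, 10**6))
        row = {
            "p_proximity": pp,
            "p_wave": pw,
            "Q": float(np.mean([r.Q for r in recs])),
            "Q_sem": _sem([r.Q for r in recs]),
            "E_avg": float(np.mean([r.E_avg for r in recs])),
            "E_avg_sem": _sem([r.E_avg for r in recs]),
            "connected_fraction": float(
                np.mean([r.connected_fraction for r in recs])
            ),
            "connected_fraction_sem": _sem([r.connected_fraction for r in recs]),
        }
        row.update(initiator_statistics(recs, ctrl_rng))
        row.update(targeted_statistics(recs))
        row.update(cdu_statistics(recs))
        rows.append(row)
        all_records.extend(recs)
    return SweepResult(
        p_proximity_values=[float(p) for p in p_proximity_values],
        p_wave_values=[float(p) for p in p_wave_values],
        R=R,
        master_seed=master_seed,
        cells=pd.DataFrame(rows),
        records=all_records,
    )


def plot_heatmaps(sweep: SweepResult, outdir, statistics: list[str] | None = None):
    """One PNG heatmap per statistic over the (p_proximity, p_wave) grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pps = sorted(sweep.p_proximity_values)
    pws = sorted(sweep.p_wave_values)
    stats = statistics or [
        c
        for c in sweep.cells.columns
        if c not in ("p_proximity", "p_wave") and not c.endswith("_sem")
    ]
    written = []
    for stat in stats:
        grid = np.full((len(pws), len(pps)), np.nan)
        for _, row in sweep.cells.iterrows():
            i = pws.index(row["p_wave"])
            j = pps.index(row["p_proximity"])
            grid[i, j] = row[stat]
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        im = ax.imshow(grid, origin="lower", aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(pps)), [f"{p:g}" for p in pps])
        ax.set_yticks(range(len(pws)), [f"{p:g}" for p in pws])
        ax.set_xlabel("p_proximity")
        ax.set_ylabel("p_wave")
        ax.set_title(stat)
        fig.colorbar(im, ax=ax)
        path = outdir / f"{stat}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
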