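"""Measurement layer: accuracy, spike sparsity, operation accounting,
weight statistics and the (tau_mem, tau_syn) grid-search driver.

The grid search trains each (model, topology, tau_mem, tau_syn) cell for a
number of independent seeds and aggregates mean +/- standard deviation of
the test accuracy together with the hidden-layer spike counts on the test
set — spikes being the proxy for dynamic energy on event-driven hardware.
Operation counts capture the complementary static cost: the multiply/add/
compare workload per spiking neuron per time step, which grows with model
complexity (IF needs no multiplier, LIF one for the membrane leak, CUBA-LIF
two plus an extra addition for its current compartment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    ModelKind,
    NetworkSpec,
    NeuronModelConfig,
    predict,
    run_network,
)
from .event_io import DatasetBundle
from .training import TrainConfig, TrainResult, init_weights, train

__all__ = [
    "GridSpec",
    "OpCount",
    "WeightStats",
    "op_count",
    "evaluate_accuracy",
    "hidden_spike_count",
    "percent_change",
    "weight_stats",
    "make_network",
    "grid_search",
    "report",
]


# ---------------------------------------------------------------------------
# Operation accounting


@dataclass(frozen=True)
class OpCount:
    """Arithmetic per spiking neuron per time step.

    N is the number of inputs (feedforward and/or recurrent) to the neuron
    and P the fraction of those inputs receiving a spike this step.
    """

    multiplications: float
    additions: float
    comparisons: float


def op_count(kind: ModelKind | str, n_inputs: float, p_spiking: float) -> OpCount:
    """Per-neuron per-step operation budget of each neuron model.

    IF integrates spikes only: N*P additions and the threshold comparison.
    LIF adds one multiplication for the membrane leak.  CUBA-LIF adds a
    second multiplication for the synaptic-current leak and one extra
    addition to fold the current into the membrane.
    """
    kind = ModelKind(kind)
    if n_inputs < 0:
        raise ValueError("n_inputs must be >= 0")
    if not 0.0 <= p_spiking <= 1.0:
        raise ValueError("p_spiking must lie in [0, 1]")
    np_ = n_inputs * p_spiking
    if kind is ModelKind.IF:
        return OpCount(0.0, np_, 1.0)
    if kind is ModelKind.LIF:
        return OpCount(1.0, np_, 1.0)
    return OpCount(2.0, np_ + 1.0, 1.0)


# ---------------------------------------------------------------------------
# Accuracy and sparsity


def evaluate_accuracy(net: NetworkSpec, bundle: DatasetBundle, chunk: int = 256) -> float:
    """Fraction of test samples whose max-over-time readout argmax matches
    the label."""
    if bundle.n_samples == 0:
        raise ValueError("empty test set")
    correct = 0
    for lo in range(0, bundle.n_samples, chunk):
        trace = run_network(bundle.x[:, lo : lo + chunk], net)
        correct += int((predict(trace) == bundle.labels[lo : lo + chunk]).sum())
    return correct / bundle.n_samples


def hidden_spike_count(
    net: NetworkSpec, bundle: DatasetBundle, chunk: int = 256
) -> tuple[float, float]:
    """(total, per-sample mean) hidden-layer spikes over a test set."""
    total = 0.0
    for lo in range(0, bundle.n_samples, chunk):
        trace = run_network(bundle.x[:, lo : lo + chunk], net)
        total += float(trace.hidden_spikes.sum())
    mean = total / bundle.n_samples if bundle.n_samples else 0.0
    return total, mean


def percent_change(baseline: float, other: float) -> float:
    """Signed percent change from ``baseline`` to ``other``."""
    if baseline == 0:
        return 0.0 if other == 0 else math.inf
    return 100.0 * (other - baseline) / baseline


# ---------------------------------------------------------------------------
# Weight statistics


@dataclass(frozen=True)
class WeightStats:
    matrix: str
    mean: float
    std: float


def weight_stats(net: NetworkSpec) -> list[WeightStats]:
    """Sample mean and population standard deviation of each weight matrix."""
    out = [WeightStats("w_in", float(net.w_in.mean()), float(net.w_in.std()))]
    if net.recurrent:
        out.append(WeightStats("v_rec", float(net.v_rec.mean()), float(net.v_rec.std())))
    out.append(WeightStats("w_out", float(net.w_out.mean()), float(net.w_out.std())))
    return out


# ---------------------------------------------------------------------------
# Grid search


@dataclass
class GridSpec:
    """Axes of the time-constant sweep.

    Model/time-constant compatibility is structural: IF admits only
    (tau_syn=0, tau_mem=inf) and LIF only tau_syn=0, so those models ignore
    the incompatible axis rather than multiplying the grid.
    """

    model_kinds: Sequence[ModelKind | str] = (ModelKind.LIF,)
    tau_mem_list: Sequence[float] = (140.0,)
    tau_syn_list: Sequence[float] = (0.0,)
    topologies: Sequence[str] = ("fsnn",)
    n_seeds: int = 3

    def cells(self):
        """Yield the valid (kind, topology, tau_mem, tau_syn) combinations."""
        for kind in self.model_kinds:
            kind = ModelKind(kind)
            for topo in self.topologies:
                if topo not in ("fsnn", "rsnn"):
                    raise ValueError(f"unknown topology {topo!r}")
                if kind is ModelKind.IF:
                    yield kind, topo, math.inf, 0.0
                    continue
                for tau_mem in self.tau_mem_list:
                    if kind is ModelKind.LIF:
                        if math.isinf(tau_mem):
                            continue
                        yield kind, topo, tau_mem, 0.0
                    else:
                        for tau_syn in self.tau_syn_list:
                            yield kind, topo, tau_mem, tau_syn

    def validate_cell(self, kind: ModelKind, tau_mem: float, tau_syn: float) -> None:
        kind = ModelKind(kind)
        if kind is ModelKind.IF and not (tau_syn == 0 and math.isinf(tau_mem)):
            raise ValueError("IF admits only tau_syn=0 and tau_mem=inf")
        if kind is ModelKind.LIF and tau_syn != 0:
            raise ValueError("LIF admits only tau_syn=0")


def make_network(
    kind: ModelKind | str,
    n_in: int,
    n_hidden: int,
    n_out: int,
    recurrent: bool,
    tau_mem_ms: float,
    tau_syn_ms: float,
    seed: int,
    dt_ms: float = 14.0,
) -> NetworkSpec:
    """Build a freshly initialized network for one grid cell."""
    kind = ModelKind(kind)
    cfg = NeuronModelConfig(kind, tau_syn_ms=tau_syn_ms, tau_mem_ms=tau_mem_ms, dt_ms=dt_ms)
    w_in, v_rec, w_out = init_weights(n_in, n_hidden, n_out, recurrent, seed)
    return NetworkSpec(
        n_in=n_in,
        n_hidden=n_hidden,
        n_out=n_out,
        recurrent=recurrent,
        w_in=w_in,
        v_rec=v_rec,
        w_out=w_out,
        hidden_cfg=cfg,
        readout_cfg=cfg,
    )


def grid_search(
    grid: GridSpec,
    train_bundle: DatasetBundle,
    test_bundle: DatasetBundle,
    train_cfg: TrainConfig,
    n_hidden: int = 200,
    master_seed: int = 0,
    per_seed_sink: Optional[list] = None,
) -> pd.DataFrame:
    """Train every valid grid cell over ``grid.n_seeds`` seeds and aggregate.

    Returns a table with one row per cell: mean/std accuracy (sample std,
    ddof=1 as soon as there are >= 2 seeds), mean hidden spikes per test
    sample, and the seed list.  ``per_seed_sink``, when given, collects the
    individual :class:`TrainResult` objects so every aggregate is auditable.
    """
    rows = []
    for kind, topo, tau_mem, tau_syn in grid.cells():
        grid.validate_cell(kind, tau_mem, tau_syn)
        accs, spikes, seeds = [], [], []
        for rep in range(grid.n_seeds):
            seed = master_seed * 1009 + rep
            net = make_network(
                kind,
                train_bundle.n_channels,
                n_hidden,
                train_bundle.n_classes,
                recurrent=(topo == "rsnn"),
                tau_mem_ms=tau_mem,
                tau_syn_ms=tau_syn,
                seed=seed,
                dt_ms=train_bundle.dt_ms,
            )
            cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed, "n_class": train_bundle.n_classes})
            result = train(
                train_bundle.x,
                train_bundle.labels,
                test_bundle.x,
                test_bundle.labels,
                net,
                cfg,
            )
            accs.append(evaluate_accuracy(net, test_bundle))
            spikes.append(hidden_spike_count(net, test_bundle)[1])
            seeds.append(seed)
            if per_seed_sink is not None:
                per_seed_sink.append(result)
        accs = np.asarray(accs)
        rows.append(
            {
                "model": kind.value,
                "topology": topo,
                "tau_mem_ms": tau_mem,
                "tau_syn_ms": tau_syn,
                "accuracy_mean": float(accs.mean()),
                "accuracy_std": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
                "hidden_spikes_mean": float(np.mean(spikes)),
                "seeds": tuple(seeds),
            }
        )
    return pd.DataFrame(rows)


def report(table: pd.DataFrame, out_dir: str | Path, name: str = "grid") -> dict[str, Path]:
    """Write the grid table as CSV plus a tau_mem x tau_syn markdown pivot.

    Missing cells render as blanks.  Returns the written paths.
    """
    if table.empty:
        raise ValueError("empty result table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    table.to_csv(csv_path, index=False)

    md_path = out_dir / f"{name}.md"
    lines = []
    for (model, topo), sub in table.groupby(["model", "topology"], sort=True):
        lines.append(f"## {model} / {topo}\n")
        pivot = sub.pivot_table(
            index="tau_mem_ms", columns="tau_syn_ms", values="accuracy_mean", aggfunc="mean"
        )
        header = "| tau_mem (ms) | " + " | ".join(
            f"tau_syn={c:g}" for c in pivot.columns
        ) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(pivot.columns) + 1))
        for tau_mem, row in pivot.iterrows():
            cells = [
                f"{v:.4f}" if np.isfinite(v) else "" for v in row.to_numpy()
            ]
            lines.append(f"| {tau_mem:g} | " + " | ".join(cells) + " |")
        lines.append("")
    md_path.write_text("\n".join(lines))
    return {"csv": csv_path, "markdown": md_path}
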