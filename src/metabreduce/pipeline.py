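"""End-to-end experiment orchestration: preprocess -> reduce -> sweep -> report.

Two experiment designs are supported:

* **no-reduction**: preprocess the table and cluster every replicate column
  directly (each independent analysis is one point), sweeping the cluster
  count and reporting validity curves plus a per-replicate membership table
  — the design that exposes stray replicates joining a foreign cluster;
* **reduced**: preprocess, collapse each region to one representative with
  one or more reduction methods, then run the same sweep per method and
  report the methods x c validity matrix and per-method membership tables
  at each index's optimal c.

All randomness derives from one master seed: the FCM run for method index
``mi`` at cluster count ``c`` uses
``SeedSequence(master, spawn_key=(mi, c))``, so runs are reproducible and
per-(method, c) streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .fcm import fit_fcm, FuzzyClusterModel
from .io import MetaboliteTable, ReducedDataset, write_reduced
from .preprocess import preprocess
from .reducers import reduce_dataset, _REDUCERS
from .validity import (
    INDEX_RULES,
    ValidityCurve,
    crisp_assign,
    silhouette_index,
    tss_index,
    xie_beni_index,
)

__all__ = ["PipelineConfig", "RunReport", "run_no_reduction", "run_reduced"]

ALL_METHODS = tuple(_REDUCERS)
ALL_INDICES = tuple(INDEX_RULES)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; serialisable to/from YAML."""

    methods: tuple[str, ...] = ("mwa",)
    indices: tuple[str, ...] = ("tss", "silhouette")
    zero_fill: float = 1e-5
    log_base: float = 10.0
    mwa_epsilon: float = 1e-5
    mwa_max_iter: int = 100
    n_neighbors: int = 5
    le_weighting: str = "binary"
    heat_sigma: float = 1.0
    c_min: int = 2
    c_max: int = 11
    m: float = 2.0
    fcm_epsilon: float = 1e-5
    fcm_max_iter: int = 100
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.methods, str):
            self.methods = (self.methods,)
        self.methods = tuple(
            m for tag in self.methods for m in (ALL_METHODS if tag == "all" else (tag,))
        )
        if isinstance(self.indices, str):
            self.indices = (self.indices,)
        self.indices = tuple(
            i for tag in self.indices for i in (ALL_INDICES if tag == "all" else (tag,))
        )
        for m in self.methods:
            if m not in ALL_METHODS:
                raise DomainError(f"unknown reduction method {m!r}")
        for i in self.indices:
            if i not in ALL_INDICES:
                raise DomainError(f"unknown validity index {i!r}")
        if self.c_min < 2 or self.c_max < self.c_min:
            raise DomainError("need 2 <= c_min <= c_max")

    def reducer_settings(self, method: str) -> dict:
        if method == "mwa":
            return dict(epsilon=self.mwa_epsilon, max_iter=self.mwa_max_iter)
        if method == "le":
            return dict(
                n_neighbors=self.n_neighbors,
                weighting=self.le_weighting,
                heat_sigma=self.heat_sigma,
            )
        if method == "lle":
            return dict(n_neighbors=self.n_neighbors)
        return {}


@dataclass
class RunReport:
    """Everything one run produced; ``save`` writes a self-describing directory."""

    config: dict
    design: str                      # "no_reduction" | "reduced"
    validity: pd.DataFrame           # columns: index, method, c, value, optimal_flag
    optimal: pd.DataFrame            # columns: method, index, optimal_c, value
    memberships: dict[str, pd.DataFrame]
    traces: pd.DataFrame             # columns: method, c, iteration, objective
    reduced: dict[str, ReducedDataset] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    def validity_matrix(self, index: str) -> pd.DataFrame:
        """c (rows) x methods (columns) matrix for one index."""
        sub = self.validity[self.validity["index"] == index]
        return sub.pivot(index="c", columns="method", values="value")

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)
        self.validity.to_csv(outdir / "validity_long.csv", index=False)
        for index in self.validity["index"].unique():
            self.validity_matrix(index).to_csv(outdir / f"validity_{index}.csv")
        self.optimal.to_csv(outdir / "optimal_c.csv", index=False)
        self.traces.to_csv(outdir / "objective_traces.csv", index=False)
        for key, df in self.memberships.items():
            df.to_csv(outdir / f"membership_{key}.csv", index=False)
        for method, ds in self.reduced.items():
            write_reduced(ds, outdir / f"reduced_{method}.csv")
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        return outdir


def _seed_for(master: int, method_index: int, c: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(method_index, c))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _index_value(
    name: str, Z: np.ndarray, model: FuzzyClusterModel
) -> float:
    if name == "tss":
        return tss_index(Z, model.U, model.V)
    if name == "xie_beni":
        return xie_beni_index(Z, model.U, model.V)
    labels = crisp_assign(model.U)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return silhouette_index(Z, labels)[0]


def _sweep(
    Z: np.ndarray, config: PipelineConfig, method: str, method_index: int, log: list[str]
) -> tuple[dict[str, ValidityCurve], dict[int, FuzzyClusterModel]]:
    n = Z.shape[0]
    if config.c_max >= n:
        raise DomainError(
            f"c_max={config.c_max} must be below the number of points n={n}"
        )
    values: dict[str, dict[int, float]] = {i: {} for i in config.indices}
    models: dict[int, FuzzyClusterModel] = {}
    for c in range(config.c_min, config.c_max + 1):
        seed = _seed_for(config.seed, method_index, c)
        model = fit_fcm(
            Z, c, m=config.m, epsilon=config.fcm_epsilon,
            max_iter=config.fcm_max_iter, seed=seed, restarts=config.restarts,
        )
        models[c] = model
        log.append(
            f"method={method} c={c} seed={seed} iterations={model.iterations} "
            f"converged={model.converged} J_m={model.objective:.6g}"
        )
        for name in config.indices:
            values[name][c] = _index_value(name, Z, model)
    curves = {
        name: ValidityCurve(name, values[name], INDEX_RULES[name])
        for name in config.indices
    }
    return curves, models


def _membership_frame(
    model: FuzzyClusterModel, point_labels: pd.DataFrame
) -> pd.DataFrame:
    labels = crisp_assign(model.U)
    df = point_labels.copy()
    df["cluster"] = labels + 1
    for i in range(model.n_clusters):
        df[f"u{i + 1}"] = model.U[i]
    return df


def _assemble(
    design: str,
    config: PipelineConfig,
    per_method: dict[str, tuple[dict[str, ValidityCurve], dict[int, FuzzyClusterModel]]],
    point_labels: dict[str, pd.DataFrame],
    reduced: dict[str, ReducedDataset],
    Zs: dict[str, np.ndarray],
    log: list[str],
) -> RunReport:
    validity_rows, optimal_rows, trace_rows = [], [], []
    memberships: dict[str, pd.DataFrame] = {}
    for method, (curves, models) in per_method.items():
        for name, curve in curves.items():
            opt = curve.optimal_c
            optimal_rows.append(
                dict(method=method, index=name, optimal_c=opt, value=curve.values[opt])
            )
            for c, v in sorted(curve.values.items()):
                validity_rows.append(
                    dict(index=name, method=method, c=c, value=v,
                         optimal_flag=int(c == opt))
                )
            memberships[f"{method}_{name}_c{opt}"] = _membership_frame(
                models[opt], point_labels[method]
            )
        for c, model in models.items():
            for it, j in enumerate(model.objective_trace):
                trace_rows.append(dict(method=method, c=c, iteration=it, objective=j))
    return RunReport(
        config=dict(asdict(config), design=design),
        design=design,
        validity=pd.DataFrame(validity_rows),
        optimal=pd.DataFrame(optimal_rows),
        memberships=memberships,
        traces=pd.DataFrame(trace_rows),
        reduced=reduced,
        log_lines=log,
    )


def run_no_reduction(table: MetaboliteTable, config: PipelineConfig) -> RunReport:
    """Preprocess and cluster all replicate columns directly (no reduction)."""
    log = [f"design=no_reduction seed={config.seed}"]
    prepped = preprocess(table, config.zero_fill, config.log_base)
    Z = prepped.values.T  # samples as points
    curves, models = _sweep(Z, config, "none", 0, log)
    labels = prepped.sample_meta.copy()
    return _assemble(
        "no_reduction", config, {"none": (curves, models)},
        {"none": labels}, {}, {"none": Z}, log,
    )


def run_reduced(table: MetaboliteTable, config: PipelineConfig) -> RunReport:
    """Preprocess, reduce each region per method, and sweep validity per method."""
    log = [f"design=reduced seed={config.seed} methods={','.join(config.methods)}"]
    prepped = preprocess(table, config.zero_fill, config.log_base)
    per_method, point_labels, reduced, Zs = {}, {}, {}, {}
    for mi, method in enumerate(config.methods):
        ds = reduce_dataset(prepped, method, **config.reducer_settings(method))
        reduced[method] = ds
        Zs[method] = ds.Z
        log.append(f"method={method} reduced to {ds.Z.shape[0]}x{ds.Z.shape[1]}")
        per_method[method] = _sweep(ds.Z, config, method, mi, log)
        point_labels[method] = pd.DataFrame(
            {"region": ds.region_labels, "origin": ds.origin_labels}
        )
    return _assemble("reduced", config, per_method, point_labels, reduced, Zs, log)


def plot_validity_curves(report: RunReport, path: str | Path) -> None:
    """One panel per index: value vs c for each method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    indices = list(report.validity["index"].unique())
    fig, axes = plt.subplots(1, len(indices), figsize=(5 * len(indices), 4))
    axes = np.atleast_1d(axes)
    for ax, index in zip(axes, indices):
        mat = report.validity_matrix(index)
        for method in mat.columns:
            ax.plot(mat.index, mat[method], marker="o", label=method)
        ax.set_xlabel("number of clusters c")
        ax.set_ylabel(index)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_objective_trace(report: RunReport, method: str, c: int, path: str | Path) -> None:
    """FCM objective J_m per iteration for one (method, c)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report.traces.query("method == @method and c == @c")
    if sub.empty:
        raise DomainError(f"no trace recorded for method={method!r}, c={c}")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sub["iteration"], sub["objective"], marker="o")
    ax.set_xlabel("iteration")
    ax.set_ylabel("J_m")
    ax.set_title(f"{method}, c={c}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
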