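"""Configuration-driven end-to-end runner.

One call to :func:`run_pipeline` executes the whole analysis on either a
simulated study or user-supplied CSV files: median-split group construction,
preprocessing and cross-group equating, network estimation, the four
structural measures with Erdos-Renyi null Z-tests, the graded partial-network
bootstrap comparison, and the unique-response McNemar test.  Outputs are
diffable CSV tables (table1 ... table6 analogues of a standard group-network
report), graph exports, and a JSON run log carrying seeds and attrition so a
run can be reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral import compare_groups, correlate_indices, median_split
from .construction import estimate_network
from .data import equate_groups, load_responses, preprocess, records_from_frame, split_matrix
from .exceptions import ConfigurationError
from .inference import DEFAULT_PROPORTIONS, bootstrap_partial, mcnemar_unique, \
    random_network_null, z_test
from .metrics import MEASURE_NAMES, measure_all
from .synthetic import simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; the seed is mandatory.

    With ``responses_path`` unset, a synthetic study is generated from the
    run seed.  ``grouping`` names the score column for the primary median
    split; ``secondary_grouping`` (optional) adds a second split analysed
    with the reduced measure set, mirroring a creativity-vs-intelligence
    study design.
    """

    seed: int
    out_dir: str = "fluencynet_run"
    responses_path: str | None = None
    scores_path: str | None = None
    grouping: str = "odt"
    secondary_grouping: str | None = "spm"
    secondary_measures: tuple[str, ...] = ("aspl", "q")
    min_producers: int = 2
    min_per_group: int = 2
    n_sims: int = 1000
    n_boot: int = 1000
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    restarts: int = 10
    n_ref: int = 100
    log_transform: tuple[str, ...] = ()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} did not parse to a mapping")
        if "seed" not in raw:
            raise ConfigurationError("config must set 'seed'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("proportions", "secondary_measures", "log_transform"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def export_graph(g: nx.Graph, path: str | Path, fmt: str | None = None) -> Path:
    """Write a graph as an edge-list CSV or GraphML (inferred from the suffix).

    Both formats round-trip node labels, including non-ASCII tokens.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "csv":
        pd.DataFrame(sorted(tuple(sorted(e)) for e in g.edges()),
                     columns=["token_a", "token_b"]).to_csv(path, index=False)
    elif fmt == "graphml":
        nx.write_graphml(g, path, encoding="utf-8")
    else:
        raise ConfigurationError(
            f"unknown graph format {fmt!r}; supported: csv, graphml"
        )
    return path


def read_graph(path: str | Path) -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    path = Path(path)
    if path.suffix == ".csv":
        edges = pd.read_csv(path, dtype=str)
        g = nx.Graph()
        g.add_edges_from(edges.itertuples(index=False, name=None))
        return g
    if path.suffix == ".graphml":
        return nx.read_graphml(path)
    raise ConfigurationError(f"unknown graph format {path.suffix!r}; supported: csv, graphml")


def _analyse_split(matrix: pd.DataFrame, scores: pd.DataFrame, config: RunConfig,
                   variable: str, measures: tuple[str, ...], out: Path,
                   tag: str) -> dict:
    """Median split -> equate -> networks -> null Z-tests -> bootstrap -> McNemar."""
    if variable not in scores.columns:
        raise ConfigurationError(f"grouping variable {variable!r} not in scores table")
    assignment = median_split(scores[variable], variable=variable)
    mat_low, mat_high = split_matrix(matrix, assignment.labels)
    # unique-response (McNemar) analysis runs on the un-equated universe
    counts, chi2, p_mc, phi = mcnemar_unique(mat_low, mat_high)
    eq_low, eq_high = equate_groups(mat_low, mat_high, config.min_per_group)

    nets = {"low": estimate_network(eq_low), "high": estimate_network(eq_high)}
    n, m = nets["low"].number_of_nodes(), nets["low"].number_of_edges()
    null = random_network_null(n, m, n_sims=config.n_sims,
                               seed=config.seed + 11, restarts=config.restarts,
                               n_ref=config.n_ref)
    empirical = {
        grp: measure_all(g, seed=config.seed + 13, restarts=config.restarts,
                         n_ref=config.n_ref)
        for grp, g in nets.items()
    }
    rows = []
    for meas in measures:
        row = {"measure": meas,
               "random_mean": null[meas].mean, "random_sd": null[meas].sd}
        for grp in ("low", "high"):
            value = empirical[grp].as_dict()[meas]
            z, pz = z_test(value, null[meas])
            row[grp] = value
            row[f"z_{grp}"], row[f"p_{grp}"] = z, pz
        rows.append(row)
    empirical_table = pd.DataFrame(rows)

    boots = bootstrap_partial(eq_low, eq_high, proportions=config.proportions,
                              n_boot=config.n_boot, seed=config.seed + 17,
                              measures=measures, restarts=config.restarts,
                              n_ref=config.n_ref)
    boot_table = pd.DataFrame([
        {"proportion": b.proportion, "measure": b.measure, "t": b.t, "p": b.p,
         "d": b.d, "df": b.df,
         "low_mean": b.low_values.mean(), "high_mean": b.high_values.mean()}
        for b in boots
    ])
    mcnemar_table = pd.DataFrame([{
        "n_total": counts.n_total, "both": counts.both,
        "high_only": counts.high_only, "low_only": counts.low_only,
        "high_pct": counts.high_pct, "low_pct": counts.low_pct,
        "chi2": chi2, "p": p_mc, "phi": phi,
    }])
    for grp, g in nets.items():
        export_graph(g, out / f"network_{tag}_{grp}.csv")
        export_graph(g, out / f"network_{tag}_{grp}.graphml")
    return {
        "assignment": assignment,
        "empirical_table": empirical_table,
        "boot_table": boot_table,
        "mcnemar_table": mcnemar_table,
        "n_nodes": n, "n_edges": m,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Returns a name -> path mapping of every file written.  Identical configs
    (same seed) produce byte-identical bundles.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.responses_path is None:
        bundle = simulate_study(seed=config.seed)
        bundle.write(out / "synthetic_input")
        records = records_from_frame(bundle.records)
        scores = bundle.scores
    else:
        records = load_responses(config.responses_path)
        if config.scores_path is None:
            raise ConfigurationError("scores_path is required with responses_path")
        scores = pd.read_csv(config.scores_path, index_col="participant")

    matrix = preprocess(records, min_producers=config.min_producers)
    matrix = matrix.loc[[p for p in matrix.index if p in scores.index]]

    numeric = scores.select_dtypes("number")
    rho, pvals = correlate_indices(numeric, log_columns=config.log_transform)

    splits = {"primary": (config.grouping, MEASURE_NAMES)}
    if config.secondary_grouping:
        splits["secondary"] = (config.secondary_grouping, config.secondary_measures)

    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=index, float_format="%.6g")
        paths[name] = path

    emit("table1_correlations", rho)
    emit("table1_pvalues", pvals)

    results = {}
    desc_rows = []
    for tag, (variable, measures) in splits.items():
        results[tag] = _analyse_split(matrix, scores, config, variable, measures,
                                      out, tag)
        assignment = results[tag]["assignment"]
        for col in numeric.columns:
            t, p, d = compare_groups(numeric[col], assignment)
            low_ids, high_ids = assignment.group("low"), assignment.group("high")
            desc_rows.append({
                "split": variable, "variable": col,
                "low_mean": numeric.loc[low_ids, col].mean(),
                "low_sd": numeric.loc[low_ids, col].std(ddof=1),
                "high_mean": numeric.loc[high_ids, col].mean(),
                "high_sd": numeric.loc[high_ids, col].std(ddof=1),
                "t": t, "p": p, "d": d,
            })
    emit("table2_group_contrasts", pd.DataFrame(desc_rows), index=False)
    emit("table3_empirical_vs_random", results["primary"]["empirical_table"], index=False)
    emit("table4_bootstrap", results["primary"]["boot_table"], index=False)
    if "secondary" in results:
        emit("table5_empirical_vs_random", results["secondary"]["empirical_table"],
             index=False)
        emit("table6_bootstrap", results["secondary"]["boot_table"], index=False)
    mcnemar_frames = [
        r["mcnemar_table"].assign(split=splits[tag][0]) for tag, r in results.items()
    ]
    emit("mcnemar_unique_responses", pd.concat(mcnemar_frames, ignore_index=True),
         index=False)

    log = {
        "fluencynet_version": __version__,
        "python": platform.python_version(),
        "networkx": nx.__version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items() if k != "out_dir"},
        "matrix_shape": list(matrix.shape),
        "splits": {tag: {"variable": splits[tag][0],
                         "n_nodes": r["n_nodes"], "n_edges": r["n_edges"]}
                   for tag, r in results.items()},
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(
        {k: v for k, v in log.items() if k != "elapsed_seconds"},
        indent=2, sort_keys=True))
    paths["run_log"] = log_path
    logger.info("pipeline finished in %.1f s; outputs in %s", log["elapsed_seconds"], out)
    return paths
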