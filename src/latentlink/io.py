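"""Plain-text interchange formats.

Everything is TSV or JSON, human-auditable and diff-able:

* panels as edge lists with columns ``t  i  j`` (tab-separated, header line,
  1-based node ids) preceded by ``# n_nodes=`` / ``# n_periods=`` comment
  lines so isolated nodes and empty periods round-trip losslessly;
* per-period dense adjacency blocks separated by ``# period t`` markers;
* node covariates as ``i  t  x1..xk`` rows;
* OTU tables with a ``taxonomy`` first column and one integer column per
  sample;
* fit results as JSON with a full config echo.

Readers validate strictly and name the offending line in parse errors.
Node ids are 1-based on disk and 0-based in memory.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import EstimationConfig, FitResult
from .model import FixedEffects, ModelParams, NetworkPanel
from .otu import OTUTable

__all__ = [
    "write_panel", "read_panel",
    "write_adjacency", "read_adjacency",
    "write_covariates", "read_covariates",
    "write_otu", "read_otu",
    "write_fit", "read_fit",
]


class ParseError(ValueError):
    pass


def write_panel(panel: NetworkPanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_nodes={panel.n_nodes}\n# n_periods={panel.n_periods}\n")
        fh.write("t\ti\tj\n")
        for t in range(1, panel.n_periods + 1):
            iu = np.triu_indices(panel.n_nodes, 1)
            mask = panel.adjacency[t - 1][iu] == 1
            for i, j in zip(iu[0][mask], iu[1][mask]):
                fh.write(f"{t}\t{i + 1}\t{j + 1}\n")


def read_panel(path, n_nodes: int | None = None, n_periods: int | None = None) -> NetworkPanel:
    path = Path(path)
    rows = []
    with path.open() as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key == "n_nodes":
                    n_nodes = int(val)
                elif key == "n_periods":
                    n_periods = int(val)
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts != ["t", "i", "j"]:
                    raise ParseError(f"{path}:{lineno}: expected header 't\\ti\\tj', got {line!r}")
                header_seen = True
                continue
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            try:
                t, i, j = (int(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if i == j:
                raise ParseError(f"{path}:{lineno}: self-edge {i}-{j}")
            rows.append((t, i, j))
    if n_nodes is None:
        n_nodes = max((max(i, j) for _, i, j in rows), default=0)
    if n_periods is None:
        n_periods = max((t for t, _, _ in rows), default=1)
    C = np.zeros((n_periods, n_nodes, n_nodes), dtype=np.int8)
    for t, i, j in rows:
        if not 1 <= t <= n_periods:
            raise ParseError(f"{path}: period {t} outside 1..{n_periods}")
        if not (1 <= i <= n_nodes and 1 <= j <= n_nodes):
            raise ParseError(f"{path}: node id outside 1..{n_nodes} in edge ({t},{i},{j})")
        C[t - 1, i - 1, j - 1] = C[t - 1, j - 1, i - 1] = 1
    return NetworkPanel(C)


def write_adjacency(panel: NetworkPanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_nodes={panel.n_nodes}\n# n_periods={panel.n_periods}\n")
        for t in range(1, panel.n_periods + 1):
            fh.write(f"# period {t}\n")
            for row in panel.adjacency[t - 1]:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_adjacency(path) -> NetworkPanel:
    path = Path(path)
    blocks, current = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# period"):
                if current:
                    blocks.append(current)
                current = []
                continue
            if line.startswith("#"):
                continue
            try:
                current.append([int(v) for v in line.split("\t")])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer entry ({exc})") from None
    if current:
        blocks.append(current)
    if not blocks:
        raise ParseError(f"{path}: no adjacency blocks found")
    return NetworkPanel(np.array(blocks, dtype=np.int8))


def write_covariates(panel: NetworkPanel, path) -> None:
    if panel.covariates is None:
        raise ValueError("panel has no covariates")
    T, N, d = panel.covariates.shape
    cols = [f"x{k + 1}" for k in range(d)]
    recs = [
        {"i": i + 1, "t": t + 1, **{c: panel.covariates[t, i, k] for k, c in enumerate(cols)}}
        for t in range(T)
        for i in range(N)
    ]
    pd.DataFrame.from_records(recs).to_csv(path, sep="\t", index=False)


def read_covariates(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.columns[:2].tolist() != ["i", "t"]:
        raise ParseError(f"{path}: first columns must be 'i' and 't'")
    N = int(df["i"].max())
    T = int(df["t"].max())
    xcols = df.columns[2:]
    X = np.full((T, N, len(xcols)), np.nan)
    X[df["t"].to_numpy() - 1, df["i"].to_numpy() - 1] = df[xcols].to_numpy()
    if np.isnan(X).any():
        raise ParseError(f"{path}: missing covariate rows for some (i, t)")
    return X


def write_otu(table: OTUTable, path) -> None:
    df = pd.DataFrame(table.counts, columns=list(table.sample_ids))
    df.insert(0, "taxonomy", list(table.taxonomy))
    df.to_csv(path, sep="\t", index=False)


def read_otu(path) -> OTUTable:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "taxonomy":
        raise ParseError(f"{path}: first column must be 'taxonomy'")
    counts = df.iloc[:, 1:].to_numpy()
    try:
        return OTUTable(counts, df["taxonomy"].tolist(), df.columns[1:].tolist())
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_fit(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    cfg = EstimationConfig(**d["config"])
    return FitResult(
        theta_hat=ModelParams(alpha=np.array(d["alpha"]), beta=np.array(d["beta"])),
        a_hat=FixedEffects(np.array(d["node_effects"]), d["pair_rule"]),
        loglik=d["loglik"],
        information=None if d["information"] is None else np.array(d["information"]),
        std_errors=None if d["std_errors"] is None else np.array(d["std_errors"]),
        converged=d["converged"],
        n_iter=d["n_iter"],
        diagnostics=d["diagnostics"],
        q=d["q"],
        config=cfg,
    )
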