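"""Readers and writers for the artifact's text formats.

One tabular dialect everywhere: TSV, UTF-8, header row, '.' decimal, floats
printed with %.12g (enough digits for an exact value round-trip at float64
display precision).  Graphs export as edge-list TSV and DOT.  Configs are
YAML; every run writes a JSON metadata sidecar for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import WorldConfig
from .simulator import Episode, MOTOR_NAMES, SIP_NAMES

FLOAT_FMT = "%.12g"


def read_timeseries(path) -> pd.DataFrame:
    """Read a labeled multivariate series (one column per channel).

    Raises ValueError naming the offending line on ragged rows or
    non-numeric cells.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(f"{path.name}: line {lineno}: expected {len(header)} cells, got {len(cells)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path.name}: line {lineno}: non-numeric cell ({exc})") from None
    return pd.DataFrame(rows, columns=header)


def write_timeseries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_matrix(labels_rows, labels_cols, values: np.ndarray, path) -> None:
    """Labeled matrix as TSV: first column holds row labels."""
    df = pd.DataFrame(np.asarray(values), index=list(labels_rows), columns=list(labels_cols))
    df.to_csv(path, sep="\t", index=True, index_label="", float_format=FLOAT_FMT)


def read_matrix(path) -> tuple[list, list, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), list(df.columns), df.to_numpy(dtype=float)


def write_graph(g, path_prefix) -> None:
    """Directed graph as edge-list TSV (<prefix>.tsv) and DOT (<prefix>.dot)."""
    prefix = Path(path_prefix)
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1.0)}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False, float_format=FLOAT_FMT
    )
    lines = ["digraph sm {"]
    for node in sorted(g.nodes):
        lines.append(f'  "{node}";')
    for u, v, d in sorted(g.edges(data=True)):
        w = d.get("weight", 1.0)
        lines.append(f'  "{u}" -> "{v}" [label="{w:.4g}"];')
    lines.append("}")
    prefix.with_suffix(".dot").write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# episodes and configs
# ---------------------------------------------------------------------------


def save_episode(episode: Episode, out_dir) -> None:
    """Episode as tidy TSVs (sips.tsv, motors.tsv) plus meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    T = episode.n_steps
    rows = []
    for i, name in enumerate(SIP_NAMES):
        rows.append(
            pd.DataFrame(
                {
                    "t": np.arange(T),
                    "entity": name,
                    "x": episode.positions[:, i, 0],
                    "y": episode.positions[:, i, 1],
                    "h": episode.haptics[:, i],
                }
            )
        )
    tidy = pd.concat(rows, ignore_index=True).sort_values(["t", "entity"], kind="stable")
    tidy.to_csv(out / "sips.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    motors = pd.DataFrame(episode.motors, columns=list(MOTOR_NAMES))
    motors.insert(0, "t", np.arange(T))
    motors.to_csv(out / "motors.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    meta = dict(episode.meta)
    meta["reset_times"] = [int(t) for t in episode.reset_times]
    meta["config"] = episode.config.to_dict()
    (out / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8")


def load_episode(in_dir) -> Episode:
    """Inverse of :func:`save_episode` (contact events are not round-tripped)."""
    src = Path(in_dir)
    tidy = read_timeseries_tidy(src / "sips.tsv")
    motors_df = read_timeseries(src / "motors.tsv")
    meta = json.loads((src / "meta.json").read_text(encoding="utf-8"))
    config = WorldConfig.from_dict(meta.pop("config"))
    T = int(tidy["t"].max()) + 1
    positions = np.empty((T, 7, 2))
    haptics = np.empty((T, 7))
    for i, name in enumerate(SIP_NAMES):
        sub = tidy[tidy["entity"] == name].sort_values("t")
        positions[:, i, 0] = sub["x"].to_numpy()
        positions[:, i, 1] = sub["y"].to_numpy()
        haptics[:, i] = sub["h"].to_numpy()
    resets = [int(t) for t in meta.pop("reset_times", [])]
    return Episode(
        positions=positions,
        haptics=haptics,
        motors=motors_df[list(MOTOR_NAMES)].to_numpy(),
        ball_vx=np.zeros(T),
        contact_flags=np.zeros((T, 2), dtype=bool),
        contact_events=[],
        reset_times=resets,
        meta=meta,
        config=config,
    )


def read_timeseries_tidy(path) -> pd.DataFrame:
    """Tidy SIP table (t, entity, x, y, h) with a non-numeric entity column."""
    df = pd.read_csv(path, sep="\t", dtype={"entity": str})
    for col in ("t", "x", "y", "h"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def save_config(config: WorldConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8")


def load_config(path) -> WorldConfig:
    return WorldConfig.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def write_sidecar(out_dir, payload: dict, name: str = "run_meta.json") -> None:
    """Provenance sidecar: command, parameters, seeds, package version."""
    from . import __version__

    payload = dict(payload)
    payload["atgraph_version"] = __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / name).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
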