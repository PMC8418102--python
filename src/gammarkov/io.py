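"""File formats: spike/trajectory TSV, transition-table JSON, stationary
TSV, coordinate-format generators, and run manifests.

All TSV files are tab-separated with one header line; lines starting with
``#`` carry metadata as ``key=value`` pairs and are ignored by generic TSV
readers.  Times are in ms and rates in Hz throughout.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cg import CTMCGenerator
from .containers import CGProjection, SpikeTrain
from .rn import TransitionTable

__all__ = [
    "write_spike_tsv", "read_spike_tsv",
    "write_trajectory_tsv", "read_trajectory_tsv",
    "write_table_json", "read_table_json",
    "write_stationary_tsv", "read_stationary_tsv",
    "write_generator_coo", "read_generator_coo",
    "write_manifest",
]


class FormatError(ValueError):
    pass


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    return meta


def write_spike_tsv(train: SpikeTrain, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_neurons={train.n_neurons} duration_ms={train.duration}"
                 f" n_e={train.n_e if train.n_e is not None else ''}\n")
        fh.write("time_ms\tneuron_id\tpopulation\n")
        pop = np.where(train.pops == 0, "E", "I")
        for t, i, p in zip(train.times, train.neurons, pop):
            fh.write(f"{float(t)!r}\t{i}\t{p}\n")  # repr round-trips exactly


def read_spike_tsv(path) -> SpikeTrain:
    meta = _read_meta(path)
    try:
        n_neurons = int(meta["n_neurons"])
        duration = float(meta["duration_ms"])
    except KeyError as e:
        raise FormatError(f"{path}: missing metadata field {e}") from e
    n_e = int(meta["n_e"]) if meta.get("n_e") else None
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    bad = df[~df["population"].isin(["E", "I"])]
    if len(bad):
        raise FormatError(
            f"{path}: invalid population at data row(s) {bad.index.tolist()[:5]}"
        )
    return SpikeTrain(
        times=df["time_ms"].to_numpy(float),
        neurons=df["neuron_id"].to_numpy(np.int64),
        pops=(df["population"] == "I").to_numpy(np.uint8),
        n_neurons=n_neurons, duration=duration, n_e=n_e,
    )


def write_trajectory_tsv(proj: CGProjection, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_ms\tn_ge\tn_gi\th_e\th_i\n")
        for row in zip(proj.times, proj.n_ge, proj.n_gi, proj.h_e, proj.h_i):
            fh.write(f"{float(row[0])!r}\t{row[1]}\t{row[2]}"
                     f"\t{row[3]}\t{row[4]}\n")


def read_trajectory_tsv(path) -> CGProjection:
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    for col in ("n_ge", "n_gi", "h_e", "h_i"):
        neg = df.index[df[col] < 0].tolist()
        if neg:
            raise FormatError(f"{path}: negative {col} at data row(s) {neg[:5]}")
    return CGProjection(df["time_ms"].to_numpy(float),
                        df["n_ge"].to_numpy(np.int64),
                        df["n_gi"].to_numpy(np.int64),
                        df["h_e"].to_numpy(np.int64),
                        df["h_i"].to_numpy(np.int64))


def write_table_json(table: TransitionTable, path) -> None:
    table.to_json(path)


def read_table_json(path) -> TransitionTable:
    return TransitionTable.from_json(path)


def write_stationary_tsv(pi: np.ndarray, gen: CTMCGenerator, path,
                         threshold: float = 0.0) -> None:
    """Stationary law as (n_ge, n_gi, h_e, h_i, probability) rows;
    entries with mass <= ``threshold`` are omitted."""
    states = gen.states()
    with open(path, "w") as fh:
        fh.write(f"# shape={','.join(map(str, gen.shape))}\n")
        fh.write("n_ge\tn_gi\th_e\th_i\tprobability\n")
        for idx in np.nonzero(pi > threshold)[0]:
            s = states[idx]
            fh.write(f"{s[0]}\t{s[1]}\t{s[2]}\t{s[3]}\t{pi[idx]:.12e}\n")


def read_stationary_tsv(path) -> tuple[np.ndarray, tuple[int, ...]]:
    meta = _read_meta(path)
    shape = tuple(int(x) for x in meta["shape"].split(","))
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    pi = np.zeros(int(np.prod(shape)))
    idx = np.ravel_multi_index(
        (df["n_ge"], df["n_gi"], df["h_e"], df["h_i"]), shape)
    pi[idx] = df["probability"].to_numpy(float)
    return pi, shape


def write_generator_coo(gen: CTMCGenerator, path) -> None:
    coo = gen.Q.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# shape={','.join(map(str, gen.shape))}"
                 f" n_states={gen.n_states} nnz={coo.nnz}\n")
        fh.write("row\tcol\trate\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v:.12e}\n")


def read_generator_coo(path) -> CTMCGenerator:
    meta = _read_meta(path)
    shape = tuple(int(x) for x in meta["shape"].split(","))
    n = int(meta["n_states"])
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip")
    Q = sp.coo_matrix(
        (df["rate"], (df["row"], df["col"])), shape=(n, n)).tocsr()
    return CTMCGenerator(Q=Q, shape=shape)


def write_manifest(path, command: str, config: dict, seed,
                   outputs: list[str], t_start: float) -> dict:
    """One manifest per CLI run: config snapshot, seeds, version, output
    inventory and wall-clock metadata — sufficient to re-run bit-identically."""
    from . import __version__
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "outputs": [
            {"path": str(p), "bytes": Path(p).stat().st_size}
            for p in outputs if Path(p).exists()
        ],
        "wall_clock_s": round(time.time() - t_start, 3),
        "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
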