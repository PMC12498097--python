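"""File formats, configuration and the synthetic-patient generator.

All interchange formats are delimited text: the measured quantity being
emulated is an integer ecDNA foci count per nucleus, so a long-format CSV
(tumor_id, region, replicate, cell_id, copies[, copies2]) is the natural
stand-in for per-nucleus image-quantification exports. Tumor snapshots are
TSV with one row per cell (x, y, copies[, copies2]) and '#' metadata lines
echoing the generating configuration and seed, so every artifact is
reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .abc import ObservedPatientData
from .lattice import SimulationConfig, TumorState, run_to_size
from .multispecies import TwoSpeciesConfig, TwoSpeciesObservedData, run_two_species
from .sampling import core_sample, leading_edge_sample, margin_samples

__all__ = [
    "CopyTableError",
    "SCHEMA_VERSION",
    "read_copy_table",
    "write_copy_table",
    "read_config",
    "write_config",
    "export_grid_snapshot",
    "import_grid_snapshot",
    "SyntheticPatient",
    "generate_synthetic_patient",
]

SCHEMA_VERSION = "ecdna-copy-table-v1"
REQUIRED_COLUMNS = ("tumor_id", "region", "replicate", "cell_id", "copies")
VALID_REGIONS = ("core", "margin", "leading_edge")


class CopyTableError(ValueError):
    """Malformed copy table."""


def _count_leading_comments(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_copy_table(path) -> pd.DataFrame:
    """Read and validate a long-format copy table (CSV, '#' comments allowed).

    Malformed rows are rejected with their 1-based file line numbers.
    """
    path = Path(path)
    offset = _count_leading_comments(path) + 2  # comments + header + 1-based
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CopyTableError(f"{path}: missing required columns {missing}")
    bad_lines = []
    copy_cols = ["copies"] + (["copies2"] if "copies2" in df.columns else [])
    for col in copy_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        bad_lines.extend((df.index[bad] + offset).tolist())
        df[col] = vals.fillna(-1).astype(np.int64)
    bad_region = ~df["region"].isin(VALID_REGIONS)
    bad_lines.extend((df.index[bad_region] + offset).tolist())
    dup = df.duplicated(subset=["tumor_id", "region", "replicate", "cell_id"], keep=False)
    bad_lines.extend((df.index[dup & ~df.duplicated(
        subset=["tumor_id", "region", "replicate", "cell_id"], keep="first")] + offset).tolist())
    if bad_lines:
        raise CopyTableError(
            f"{path}: invalid rows at line(s) {sorted(set(bad_lines))}"
        )
    return df


def write_copy_table(df: pd.DataFrame, path, metadata: Optional[Mapping] = None) -> None:
    """Write a copy table with a schema-version header comment."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CopyTableError(f"refusing to write table missing columns {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema={SCHEMA_VERSION}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def read_config(path) -> dict:
    """Flat key-value simulation config (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def export_grid_snapshot(state: TumorState, path) -> None:
    """Lossless TSV snapshot: '#' metadata lines then x, y, copies[, copies2]."""
    path = Path(path)
    meta = {"time": state.time, "status": state.status, "seed": state.seed}
    if state.config is not None:
        meta.update(state.config.to_dict())
    cols = {"x": state.xs, "y": state.ys}
    if state.two_species:
        cols["copies"] = state.copies[:, 0]
        cols["copies2"] = state.copies[:, 1]
    else:
        cols["copies"] = state.copies
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)


def import_grid_snapshot(path) -> TumorState:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    coords = list(zip(df["x"], df["y"]))
    if len(set(coords)) != len(coords):
        raise ValueError(f"{path}: overlapping lattice coordinates")
    if "copies2" in df.columns:
        copies = df[["copies", "copies2"]].to_numpy()
    else:
        copies = df["copies"].to_numpy()
    seed = meta.get("seed")
    return TumorState(
        df["x"].to_numpy(), df["y"].to_numpy(), copies,
        time=float(meta.get("time", 0.0)), status=meta.get("status", "reached"),
        seed=None if seed in (None, "None") else int(seed), info=meta,
    )


# ---------------------------------------------------------------------------
# synthetic patients
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    """A simulated stand-in for one patient's multiregion FISH measurements."""

    truth: dict
    table: pd.DataFrame
    seed: int
    tumor_id: str
    checksum: str

    def observed(self) -> ObservedPatientData:
        return ObservedPatientData.from_copy_table(self.table, self.tumor_id)

    def observed_two_species(self) -> TwoSpeciesObservedData:
        df = self.table
        core = df.loc[df.region == "core", ["copies", "copies2"]].to_numpy()
        margins = [g[["copies", "copies2"]].to_numpy()
                   for _, g in df[df.region == "margin"].groupby("replicate")]
        return TwoSpeciesObservedData(core=core, margins=margins, tumor_id=self.tumor_id)

    def write(self, prefix: Union[str, Path]) -> None:
        prefix = Path(prefix)
        write_copy_table(self.table, prefix.with_suffix(".csv"),
                         metadata={"seed": self.seed, "checksum": self.checksum})
        sidecar = dict(self.truth, seed=self.seed, checksum=self.checksum,
                       tumor_id=self.tumor_id)
        prefix.with_suffix(".truth.json").write_text(json.dumps(sidecar, indent=2))


def _table_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def generate_synthetic_patient(
    truth: Mapping,
    region_sizes: Mapping,
    seed: int = 0,
    n_final: int = 10_000,
    tumor_id: str = "synthetic",
    max_retries: int = 5,
) -> SyntheticPatient:
    """Simulate a tumor at known parameters and sample it like a patient.

    ``truth`` holds either single-species parameters (k, s, q[, d]) or
    two-species parameters (k1, k2, s_p, s_m, rho[, q, d]). ``region_sizes``
    maps 'core' to a cell count, 'margins' to a list of counts, and optionally
    'leading_edge' to a count. No copy filtering is applied (filtering is the
    consumer's job). Extinct runs are retried with the next derived seed.
    """
    rng = np.random.default_rng(seed)
    sizes_margins = list(region_sizes.get("margins", []))
    if "core" not in region_sizes or not sizes_margins:
        raise ValueError("region_sizes needs 'core' and a non-empty 'margins' list")
    two_species = "k1" in truth
    state = None
    for _ in range(max_retries):
        run_seed = int(rng.integers(1, 2**31 - 1))
        cfg = SimulationConfig(
            k=0 if two_species else int(truth["k"]),
            s=0.0 if two_species else float(truth.get("s", 0.0)),
            q=truth.get("q", np.inf), d=float(truth.get("d", 0.0)),
            n_final=n_final, seed=run_seed,
        )
        if two_species:
            tsc = TwoSpeciesConfig(
                k1=int(truth["k1"]), k2=int(truth["k2"]),
                s_p=float(truth.get("s_p", 0.0)), s_m=float(truth.get("s_m", 0.0)),
                rho=float(truth.get("rho", 0.0)),
            )
            state = run_two_species(tsc, cfg)
        else:
            state = run_to_size(cfg)
        if state.status == "reached":
            break
    if state is None or state.status != "reached":
        raise RuntimeError(f"no surviving tumor in {max_retries} attempts")

    srng = np.random.default_rng(int(rng.integers(1, 2**31 - 1)))
    samples = [("core", 0, core_sample(state, int(region_sizes["core"]), rng=srng))]
    for rep, n in enumerate(sizes_margins):
        samples.append(("margin", rep,
                        margin_samples(state, int(n), count=1, rng=srng)[0]))
    if region_sizes.get("leading_edge"):
        samples.append(("leading_edge", 0,
                        leading_edge_sample(state, int(region_sizes["leading_edge"]), rng=srng)))

    rows = []
    for region, rep, sample in samples:
        counts = np.asarray(sample.counts)
        for cid in range(len(counts)):
            row = dict(tumor_id=tumor_id, region=region, replicate=rep, cell_id=cid)
            if counts.ndim == 2:
                row["copies"] = int(counts[cid, 0])
                row["copies2"] = int(counts[cid, 1])
            else:
                row["copies"] = int(counts[cid])
            rows.append(row)
    table = pd.DataFrame(rows)
    return SyntheticPatient(
        truth=dict(truth, n_final=n_final), table=table, seed=seed,
        tumor_id=tumor_id, checksum=_table_checksum(table),
    )
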