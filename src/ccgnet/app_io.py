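"""End-user I/O: pair lists, screening reports, checkpoints, run manifests.

Canonical SMILES (RDKit) is the single identity authority for molecules:
pair lists are canonicalized on read and duplicate unordered pairs are
collapsed with a warning. Checkpoints are single-file archives carrying the
weights, the frozen feature-layout version, the architecture config and
seeds, plus a SHA-256 integrity checksum; a layout mismatch or tampered
file refuses to load.
"""

from __future__ import annotations

import datetime
import hashlib
import io
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurize import FEATURE_LAYOUT_VERSION
from .network import CCGNet
from .training import EnsembleModel

__all__ = [
    "SchemaError",
    "IntegrityError",
    "EXIT_OK",
    "EXIT_SCHEMA",
    "EXIT_NUMERIC",
    "EXIT_IO",
    "read_pairs_csv",
    "write_pairs_csv",
    "write_report",
    "save_checkpoint",
    "load_checkpoint",
    "save_ensemble",
    "load_ensemble",
    "RunManifest",
    "write_manifest",
]

EXIT_OK, EXIT_SCHEMA, EXIT_NUMERIC, EXIT_IO = 0, 2, 3, 4


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


class IntegrityError(RuntimeError):
    """Checkpoint failed its checksum or version check."""


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def read_pairs_csv(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a labeled (or unlabeled) coformer pair list.

    Required columns: id, coformer_a, coformer_b; optional label in {0, 1}.
    SMILES are canonicalized; rows with unparseable SMILES are dropped with
    a per-row warning (or raise under ``strict``); duplicate unordered pairs
    collapse to their first occurrence with a warning.
    """
    df = pd.read_csv(path)
    required = {"id", "coformer_a", "coformer_b"}
    if not required <= set(df.columns):
        raise SchemaError(f"pair CSV needs columns {sorted(required)}, got {list(df.columns)}")
    has_label = "label" in df.columns
    if has_label and not set(df["label"].dropna().unique()) <= {0, 1}:
        raise SchemaError("label column must be binary 0/1")

    rows, seen = [], set()
    for r in df.itertuples(index=False):
        ca, cb = _canonical(str(r.coformer_a)), _canonical(str(r.coformer_b))
        if ca is None or cb is None:
            msg = f"row {r.id}: unparseable SMILES"
            if strict:
                raise SchemaError(msg)
            warnings.warn(msg)
            continue
        key = frozenset((ca, cb))
        if key in seen:
            warnings.warn(f"row {r.id}: duplicate unordered pair dropped")
            continue
        seen.add(key)
        row = {"id": r.id, "coformer_a": ca, "coformer_b": cb}
        if has_label:
            row["label"] = int(r.label)
        rows.append(row)
    return pd.DataFrame(rows)


def write_pairs_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _attention_html(weights: np.ndarray) -> str:
    mean_w = weights.mean(axis=1)
    lo, hi = mean_w.min(), mean_w.max()
    scale = (mean_w - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_w)
    spans = [
        f'<span style="background: rgba(255,0,0,{s:.2f})">{w:.3f}</span>'
        for w, s in zip(mean_w, scale)
    ]
    return " ".join(spans)


def write_report(
    table: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    attention: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a ranked screening report (descending summed score preserved).

    ``fmt='html'`` renders a table; when per-pair attention weights are
    supplied they are embedded as red-intensity color maps per atom.
    """
    path = Path(path)
    if table.empty:
        warnings.warn("empty screening report")
    if fmt == "csv":
        out = table.copy()
        if "member_scores" in out.columns:
            out["member_scores"] = out["member_scores"].map(
                lambda xs: ";".join(f"{x:.6f}" for x in xs)
            )
        out.to_csv(path, index=False)
    elif fmt == "html":
        out = table.copy()
        if attention:
            out["attention"] = [
                _attention_html(attention[i]) if i in attention else ""
                for i in out["id"]
            ]
        html = out.to_html(index=False, escape=False)
        path.write_text(f"<html><body>{html}</body></html>")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


# --- checkpoints ----------------------------------------------------------------------

def _arrays_digest(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def save_checkpoint(model: CCGNet, path: str | Path, **meta) -> None:
    """Single-file model archive with config, layout version and checksum."""
    state = model.state()
    arrays = {k: np.asarray(v) for k, v in state["arrays"].items()}
    meta_block = {
        "feature_layout": FEATURE_LAYOUT_VERSION,
        "config": state["config"],
        "checksum": _arrays_digest(arrays),
        **meta,
    }
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta_block).encode(), dtype=np.uint8),
             **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> CCGNet:
    import zipfile

    try:
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
            meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
    except (OSError, ValueError, KeyError, zipfile.BadZipFile, json.JSONDecodeError) as exc:
        raise IntegrityError(f"unreadable checkpoint {path}: {exc}") from exc
    if meta.get("feature_layout") != FEATURE_LAYOUT_VERSION:
        raise IntegrityError(
            f"checkpoint layout {meta.get('feature_layout')!r} does not match "
            f"{FEATURE_LAYOUT_VERSION!r}"
        )
    if _arrays_digest(arrays) != meta.get("checksum"):
        raise IntegrityError(f"checksum mismatch in {path}: file corrupt or tampered")
    return CCGNet.from_state({"config": meta["config"], "arrays": arrays})


def save_ensemble(ensemble: EnsembleModel, directory: str | Path, **meta) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(ensemble.members):
        save_checkpoint(member, directory / f"member_{i:02d}.ckpt", member_index=i, **meta)


def load_ensemble(directory: str | Path) -> EnsembleModel:
    paths = sorted(Path(directory).glob("member_*.ckpt"))
    if not paths:
        raise IntegrityError(f"no checkpoint members found in {directory}")
    return EnsembleModel(members=[load_checkpoint(p) for p in paths])


# --- run manifests --------------------------------------------------------------------

@dataclass
class RunManifest:
    command: str
    seed: int | None
    config: dict
    input_hashes: dict
    feature_layout: str = FEATURE_LAYOUT_VERSION
    package_version: str = "0.1.0"
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None = None,
    config: dict | None = None,
    inputs: list[str | Path] = (),
) -> Path:
    """Record enough provenance to re-run a CLI command reproducibly."""
    manifest = RunManifest(
        command=command,
        seed=seed,
        config=config or {},
        input_hashes={str(p): _file_hash(p) for p in inputs if Path(p).exists()},
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2))
    return path
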