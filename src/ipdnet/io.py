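"""Configuration, serialization and reporting.

Configs are TOML (or YAML) files with sections [task], [train], [ddl] and
[dcls], each mapping onto the corresponding dataclass; unknown keys are
rejected so typos fail loudly.  Trained runs round-trip through HDF5 with
per-dataset SHA-256 checksums recorded in the file, verified on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any, Dict, Optional

import h5py
import numpy as np
import yaml

from .delays import DCLSConfig, DDLConfig
from .network import NetworkParams
from .task import TaskConfig
from .training import EvalReport, TrainConfig, TrainResult

__all__ = ["load_config", "dump_config", "save_run", "load_run",
           "make_report", "CONFIG_SECTIONS"]

CONFIG_SECTIONS = {
    "task": TaskConfig,
    "train": TrainConfig,
    "ddl": DDLConfig,
    "dcls": DCLSConfig,
}


def _build_section(name: str, cls, data: Dict[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section [{name}]; "
            f"allowed: {sorted(known)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"config section [{name}]: {err}") from err


def load_config(path) -> Dict[str, Any]:
    """Parse and validate a TOML/YAML config into dataclass sections.

    Missing sections get all-default instances; defaults for omitted keys
    are filled by the dataclasses themselves.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raw = tomllib.loads(path.read_text())
    unknown = set(raw) - set(CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return {name: _build_section(name, cls, raw.get(name, {}))
            for name, cls in CONFIG_SECTIONS.items()}


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(str(v))


def dump_config(cfg: Dict[str, Any], path) -> None:
    """Write config sections back to TOML (load -> dump -> load idempotent)."""
    lines = []
    for name in CONFIG_SECTIONS:
        section = cfg[name]
        lines.append(f"[{name}]")
        for f in dataclasses.fields(section):
            v = getattr(section, f.name)
            if v is None:
                continue
            lines.append(f"{f.name} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ----------------------------------------------------------------------
# HDF5 runs


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def save_run(result: TrainResult, path) -> None:
    """Serialize a TrainResult (weights, history, metrics, config) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    p = result.params
    with h5py.File(path, "w") as f:
        datasets = {
            "W_ih": p.w_ih, "W_ho": p.w_ho,
            "loss_history": np.asarray(result.loss_history),
            "confusion": result.metrics.confusion,
            "hidden_rates": result.metrics.hidden_rates,
        }
        if p.sign_mask_ih is not None:
            datasets["sign_mask_ih"] = np.asarray(p.sign_mask_ih, dtype=np.int8)
        if p.sign_mask_ho is not None:
            datasets["sign_mask_ho"] = np.asarray(p.sign_mask_ho, dtype=np.int8)
        manifest = {}
        for name, arr in datasets.items():
            f.create_dataset(name, data=arr)
            manifest[name] = _checksum(np.asarray(arr))
        f.attrs["tau_hidden"] = p.tau_hidden
        f.attrs["tau_readout"] = p.tau_readout
        f.attrs["v_th"] = p.v_th
        f.attrs["beta"] = p.beta
        f.attrs["accuracy"] = result.metrics.accuracy
        f.attrs["mae_deg"] = result.metrics.mae_deg
        f.attrs["n_test"] = result.metrics.n_test
        f.attrs["manifest"] = json.dumps(manifest)
        if result.task is not None:
            f.attrs["task_config"] = json.dumps(dataclasses.asdict(result.task))
        if result.config is not None:
            f.attrs["train_config"] = json.dumps(dataclasses.asdict(result.config))


def load_run(path, force: bool = False) -> TrainResult:
    """Load a TrainResult saved by :func:`save_run`, verifying checksums."""
    with h5py.File(path, "r") as f:
        required = ("W_ih", "W_ho", "loss_history", "confusion", "hidden_rates")
        for name in required:
            if name not in f:
                raise KeyError(f"run file {path} is missing dataset '{name}'")
        manifest = json.loads(f.attrs.get("manifest", "{}"))
        arrays = {name: f[name][...] for name in f.keys()}
        if not force:
            for name, digest in manifest.items():
                if _checksum(arrays[name]) != digest:
                    raise IOError(
                        f"checksum mismatch for dataset '{name}' in {path}; "
                        "file is corrupt (pass force=True to load anyway)")
        params = NetworkParams(
            w_ih=arrays["W_ih"], w_ho=arrays["W_ho"],
            tau_hidden=float(f.attrs["tau_hidden"]),
            tau_readout=float(f.attrs["tau_readout"]),
            beta=float(f.attrs["beta"]),
            sign_mask_ih=arrays.get("sign_mask_ih"),
            sign_mask_ho=arrays.get("sign_mask_ho"),
        )
        metrics = EvalReport(
            accuracy=float(f.attrs["accuracy"]),
            mae_deg=float(f.attrs["mae_deg"]),
            confusion=arrays["confusion"],
            hidden_rates=arrays["hidden_rates"],
            n_test=int(f.attrs["n_test"]),
        )
        task = None
        if "task_config" in f.attrs:
            task = TaskConfig(**json.loads(f.attrs["task_config"]))
        cfg = None
        if "train_config" in f.attrs:
            cfg = TrainConfig(**json.loads(f.attrs["train_config"]))
    return TrainResult(params=params, loss_history=arrays["loss_history"],
                       metrics=metrics, config=cfg, task=task)


# ----------------------------------------------------------------------
# Reports


def make_report(result: TrainResult, out_dir,
                analysis: Optional[Dict[str, Any]] = None,
                figures: bool = False) -> Dict[str, Any]:
    """Write metrics JSON + confusion CSV (+ optional figures); return the dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "accuracy": result.metrics.accuracy,
        "mae_deg": result.metrics.mae_deg,
        "hidden_rates": result.metrics.hidden_rates.tolist(),
        "n_test": result.metrics.n_test,
        "final_loss": float(np.asarray(result.loss_history)[-1])
        if len(result.loss_history) else None,
    }
    if analysis:
        report["analysis"] = analysis
    (out / "metrics.json").write_text(json.dumps(report, indent=2,
                                                 sort_keys=True))
    np.savetxt(out / "confusion.csv", result.metrics.confusion,
               fmt="%d", delimiter=",")
    if figures:
        _write_figures(result, out)
    return report


def _write_figures(result: TrainResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].plot(result.loss_history)
    axes[0].set(xlabel="epoch", ylabel="loss", title="Training loss")
    im = axes[1].imshow(result.metrics.confusion, origin="lower",
                        aspect="auto")
    axes[1].set(xlabel="estimated class", ylabel="true class",
                title="Confusion")
    fig.colorbar(im, ax=axes[1])
    axes[2].bar(np.arange(len(result.metrics.hidden_rates)),
                result.metrics.hidden_rates)
    axes[2].set(xlabel="hidden neuron", ylabel="rate (sp/s)",
                title="Hidden firing rates")
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (w, name) in zip(axes, ((result.params.w_ih, "W_ih"),
                                    (result.params.w_ho, "W_ho"))):
        im = ax.imshow(w, aspect="auto", cmap="coolwarm",
                       vmin=-np.abs(w).max(), vmax=np.abs(w).max())
        ax.set(title=name)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out / "weights.png", dpi=120)
    plt.close(fig)
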