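"""Versioned model archives.

A trained model (hidden layer, output weights, weighting scheme, optional
PCA model) is stored as a single ``.npz`` archive together with a JSON
manifest that records the format version and a SHA-256 checksum over the
array payload. Loading verifies the checksum and refuses tampered or
truncated archives, so persisted models reproduce their training-time
scores bit for bit.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import numpy as np

from sipwelm.features import MinMaxScaler, PCAModel
from sipwelm.welm import HiddenLayer, WeightScheme, WELMModel

FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Raised for unreadable, incompatible or tampered model archives."""


def _payload_checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        arr = np.ascontiguousarray(arrays[key])
        h.update(str(arr.dtype).encode())
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    return h.hexdigest()


def save_model(
    model: WELMModel,
    path,
    pca: PCAModel | None = None,
    scaler: MinMaxScaler | None = None,
    feature_stage: str = "lag",
) -> None:
    """Write a WELM model (and its PCA model / input scaler, if any) to ``path``."""
    arrays = {
        "input_weights": model.hidden.input_weights,
        "biases": model.hidden.biases,
        "beta": model.beta,
        "sample_weights": model.scheme.per_sample_weights,
    }
    if pca is not None:
        arrays["pca_mean"] = pca.mean
        arrays["pca_components"] = pca.components
        arrays["pca_explained_variance"] = pca.explained_variance
    if scaler is not None:
        arrays["scaler_lo"] = scaler.lo
        arrays["scaler_hi"] = scaler.hi
    manifest = {
        "format_version": FORMAT_VERSION,
        "activation": model.hidden.activation,
        "hidden_seed": model.hidden.seed,
        "C": model.C,
        "scheme": model.scheme.name,
        "solver_form": model.solver_form,
        "feature_stage": feature_stage,
        "has_pca": pca is not None,
        "has_scaler": scaler is not None,
        "checksum": _payload_checksum(arrays),
    }
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with open(path, "wb") as fh:
        fh.write(json.dumps(manifest).encode() + b"\n")
        fh.write(buf.getvalue())


def load_model(path) -> tuple[WELMModel, PCAModel | None, MinMaxScaler | None, str]:
    """Read an archive back; returns (model, pca, scaler, feature_stage).

    Raises :class:`ArchiveError` if the checksum does not match the payload.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.readline()
        payload = fh.read()
    try:
        manifest = json.loads(header.decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ArchiveError(f"{path}: unreadable manifest") from exc
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ArchiveError(
            f"{path}: unsupported format version {manifest.get('format_version')}"
        )
    try:
        npz = np.load(io.BytesIO(payload))
        arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ArchiveError(f"{path}: unreadable array payload") from exc
    if _payload_checksum(arrays) != manifest["checksum"]:
        raise ArchiveError(f"{path}: checksum mismatch — archive corrupt or tampered")
    hidden = HiddenLayer(
        input_weights=arrays["input_weights"],
        biases=arrays["biases"],
        activation=manifest["activation"],
        seed=manifest["hidden_seed"],
    )
    model = WELMModel(
        hidden=hidden,
        beta=arrays["beta"],
        C=manifest["C"],
        scheme=WeightScheme(
            name=manifest["scheme"], per_sample_weights=arrays["sample_weights"]
        ),
        solver_form=manifest["solver_form"],
    )
    pca = None
    if manifest["has_pca"]:
        pca = PCAModel(
            mean=arrays["pca_mean"],
            components=arrays["pca_components"],
            explained_variance=arrays["pca_explained_variance"],
        )
    scaler = None
    if manifest.get("has_scaler"):
        scaler = MinMaxScaler(lo=arrays["scaler_lo"], hi=arrays["scaler_hi"])
    return model, pca, scaler, manifest["feature_stage"]
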