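"""Persistence of fitted pair-model sets.

An archive is a single zip file holding ``manifest.json`` (method, feature
names, fit metadata, per-pair model kinds) and ``models.joblib`` with the
fitted model objects themselves.  The manifest makes the archive
self-describing; the joblib payload carries the numerical state, including
the scikit-learn SVM objects in their standard persistence format.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import joblib

from .networks import PairModelSet

_FORMAT_VERSION = 1


def save_pair_models(models: PairModelSet, path: str | Path) -> None:
    path = Path(path)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "method": models.method,
        "feature_names": models.feature_names,
        "n_pairs": len(models.models),
        "fit_metadata": {
            "seed": models.fit_metadata.get("seed"),
            "n_fit_samples": models.fit_metadata.get("n_fit_samples"),
            "degenerate_pairs": [list(p) for p in
                                 models.fit_metadata.get("degenerate_pairs", [])],
        },
        "pair_model_kinds": {
            f"{i},{j}": type(m).__name__ for (i, j), m in models.models.items()
        },
    }
    buf = io.BytesIO()
    joblib.dump(models, buf)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        zf.writestr("models.joblib", buf.getvalue())


def load_pair_models(path: str | Path) -> PairModelSet:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        models = joblib.load(io.BytesIO(zf.read("models.joblib")))
    if not isinstance(models, PairModelSet):
        raise ValueError("archive does not contain a pair-model set")
    return models
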