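"""Distilling deep features into a compact biomarker panel.

For each of the K deep features, candidate raw features (genes, or radiomic
features) are ranked by absolute Pearson correlation with that deep feature;
the top ``n_top`` candidates are then re-ranked by their median absolute
deviation (MAD) across the training cohort and the ``n_keep`` most variable
are kept. The union over the K deep features, deduplicated by first
occurrence, is the signature — a panel small enough for a targeted assay
that still tracks the subtype embedding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd


def mad(values) -> float:
    """Median absolute deviation, unscaled: ``median(|x - median(x)|)``."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty vector")
    return float(np.median(np.abs(x - np.median(x))))


@dataclass
class SignatureFeature:
    """One kept panel member with its selection provenance."""

    feature_id: str
    deep_index: int  # 0-based index of the deep feature that selected it
    r: float  # Pearson correlation with that deep feature
    sign: int  # sign of r
    mad: float


@dataclass
class Signature:
    """Ordered, unique panel of distilled features."""

    features: list[SignatureFeature]
    n_top: int
    n_keep: int
    modality: str = "gene"

    def __post_init__(self) -> None:
        ids = self.feature_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("signature features must be unique")

    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def to_json(self, path) -> None:
        doc = {
            "modality": self.modality,
            "n_top": self.n_top,
            "n_keep": self.n_keep,
            "features": [asdict(f) for f in self.features],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            doc = json.load(fh)
        feats = [SignatureFeature(**f) for f in doc["features"]]
        return cls(feats, doc["n_top"], doc["n_keep"], doc["modality"])


def correlate_features(
    raw: pd.DataFrame, deep: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of every raw feature with every deep feature.

    ``raw`` is samples x features, ``deep`` samples x K, aligned on index.
    Returns the features x K correlation matrix and the list of raw features
    with zero variance (their correlations are set to 0 and they are flagged
    out of candidacy). Fewer than 3 samples is an error — the correlation
    carries no inferential content below that.
    """
    if list(raw.index) != list(deep.index):
        if set(raw.index) != set(deep.index):
            raise ValueError("raw and deep feature matrices cover different samples")
        deep = deep.loc[raw.index]
    n = len(raw)
    if n < 3:
        raise ValueError("correlation requires at least 3 samples")
    X = raw.to_numpy(dtype=float)
    D = deep.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Dc = D - D.mean(axis=0)
    xs = Xc.std(axis=0)
    ds = Dc.std(axis=0)
    flagged = [str(c) for c, s in zip(raw.columns, xs) if s == 0]
    xs_safe = np.where(xs == 0, 1.0, xs)
    ds_safe = np.where(ds == 0, 1.0, ds)
    corr = (Xc / xs_safe).T @ (Dc / ds_safe) / n
    corr[xs == 0, :] = 0.0
    corr[:, ds == 0] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=raw.columns, columns=deep.columns), flagged


def select_signature(
    corr: pd.DataFrame,
    raw: pd.DataFrame,
    n_top: int = 10,
    n_keep: int = 3,
    flagged: list[str] | None = None,
    per_sign: bool = False,
    modality: str = "gene",
) -> Signature:
    """Correlation-then-MAD selection, one slate per deep feature.

    Per deep feature: rank by ``|r|`` descending (ties by feature id), take
    the ``n_top`` candidates — or, with ``per_sign``, ``n_top`` per
    correlation sign — then rank those by MAD descending (ties by feature
    id) and keep ``n_keep``. The union across deep features is deduplicated
    by first occurrence, so the panel never exceeds ``K * n_keep`` members.
    """
    if n_keep > n_top:
        raise ValueError("n_keep must not exceed n_top")
    flagged = set(flagged or [])
    candidates_all = [str(f) for f in corr.index if str(f) not in flagged]
    if len(candidates_all) < n_top:
        raise ValueError(
            f"only {len(candidates_all)} non-degenerate features available, "
            f"need at least n_top={n_top}"
        )
    mads = {f: mad(raw[f].to_numpy()) for f in candidates_all}
    kept: list[SignatureFeature] = []
    seen: set[str] = set()
    for k, col in enumerate(corr.columns):
        r = corr[col]
        if per_sign:
            pos = [f for f in candidates_all if r[f] > 0]
            neg = [f for f in candidates_all if r[f] < 0]
            pos.sort(key=lambda f: (-abs(r[f]), f))
            neg.sort(key=lambda f: (-abs(r[f]), f))
            slate = pos[:n_top] + neg[:n_top]
        else:
            slate = sorted(candidates_all, key=lambda f: (-abs(r[f]), f))[:n_top]
        slate.sort(key=lambda f: (-mads[f], f))
        for f in slate[:n_keep]:
            if f in seen:
                continue
            seen.add(f)
            kept.append(
                SignatureFeature(
                    feature_id=f,
                    deep_index=k,
                    r=float(r[f]),
                    sign=int(np.sign(r[f])),
                    mad=mads[f],
                )
            )
    return Signature(kept, n_top, n_keep, modality)
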