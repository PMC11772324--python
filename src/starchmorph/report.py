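"""Report assembly: per-sample summaries, expression-phenotype correlations
and letter-annotated group tables, with run metadata for reproducibility."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .stats import pearson_correlation, tukey_cld

__all__ = ["build_report"]

_REQUIRED = ("shapes",)


def _sample_summary(shapes: pd.DataFrame, sizes: pd.DataFrame | None) -> pd.DataFrame:
    if "sample" not in shapes.columns:
        shapes = shapes.assign(sample="sample")
    agg = shapes.groupby("sample").agg(
        n_granules=("aspect_ratio", "size"),
        mean_aspect_ratio=("aspect_ratio", "mean"),
        mean_circularity=("circularity", "mean"),
        multi_hilum_freq=("n_hila", lambda v: float((v >= 2).mean())),
    )
    if sizes is not None and len(sizes):
        idx = sizes.set_index("sample") if "sample" in sizes.columns else sizes
        agg = agg.join(idx, how="left")
    return agg.reset_index()


def _correlations(expression: pd.DataFrame) -> pd.DataFrame:
    pheno_cols = [c for c in expression.columns if c not in ("sample", "expression")]
    rows = []
    for col in pheno_cols:
        sub = expression[["expression", col]].dropna()
        r, p, n = pearson_correlation(sub["expression"], sub[col])
        rows.append(dict(phenotype=col, r=r, p=p, n=n))
    return pd.DataFrame(rows)


def _letter_tables(groups: dict[str, list], alpha: float) -> dict[str, pd.DataFrame]:
    out = {}
    for trait, gs in groups.items():
        cld = tukey_cld(gs, alpha=alpha)
        out[trait] = pd.DataFrame(
            dict(group=cld.labels, letters=[cld.letters[l] for l in cld.labels])
        )
    return out


def build_report(
    shapes: pd.DataFrame | None = None,
    sizes: pd.DataFrame | None = None,
    assays: pd.DataFrame | None = None,
    groups: dict | None = None,
    expression: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    config: dict | None = None,
    alpha: float = 0.05,
) -> dict:
    """Assemble the analysis outputs into one report bundle.

    ``shapes`` (required): per-granule shape records, optionally with a
    ``sample`` column.  ``sizes``: per-sample gate fractions.  ``assays``:
    per-sample composition values.  ``groups``: mapping trait -> group
    summaries / raw groups for letter-annotated tables.  ``expression``:
    per-line table with an ``expression`` column and phenotype columns for
    the correlation table.  Writing to ``out_dir`` is byte-deterministic
    for a fixed input and config.
    """
    if shapes is None or len(shapes) == 0:
        raise ValueError("missing required stage output: shapes")
    bundle: dict = {"summary": _sample_summary(shapes, sizes)}
    if assays is not None and len(assays):
        bundle["assays"] = assays
    if expression is not None and len(expression):
        bundle["correlations"] = _correlations(expression)
    if groups:
        bundle["letters"] = _letter_tables(groups, alpha)
    cfg = dict(config or {})
    meta = dict(
        seed=seed,
        alpha=alpha,
        config=cfg,
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
    )
    bundle["metadata"] = meta
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["summary"].to_csv(out / "summary.csv", index=False)
        if "assays" in bundle:
            bundle["assays"].to_csv(out / "assays.csv", index=False)
        if "correlations" in bundle:
            bundle["correlations"].to_csv(out / "correlations.csv", index=False)
        for trait, tab in bundle.get("letters", {}).items():
            tab.to_csv(out / f"letters_{trait}.csv", index=False)
        with open(out / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
    return bundle
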