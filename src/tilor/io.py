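"""Reading genotype tables and writing analysis reports as delimited text.

The genotype reader accepts any header + rows table with a nameable 0/1
phenotype column, and additionally the PLINK ``.raw`` dialect
(FID/IID/PAT/MAT/SEX/PHENOTYPE metadata columns, phenotype coded 1/2).
All reports are plain TSV with ``#`` header lines that embed the seed and
the effective configuration, and floats written at full precision so a
written report re-parses losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult
from .model import (
    GenotypeMatrix,
    ThresholdLinkParams,
    TILoRParams,
    below_threshold_fractions,
)

__all__ = [
    "read_genotype_table",
    "write_fit_report",
    "read_fit_report",
    "write_table_report",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_FLOAT_FMT = "%.17g"


def read_genotype_table(
    path, delimiter: str = "\t", phenotype_column: str = "phenotype"
) -> GenotypeMatrix:
    """Parse a subjects × SNPs table with one binary phenotype column.

    Genotype cells must be integers in {0, 1, 2}; the phenotype in {0, 1}
    (or 1/2 in the PLINK-.raw dialect, remapped to 0/1).  Any missing,
    non-integer or out-of-range cell raises a parse error naming the
    offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file is empty") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")

    plink = all(c in df.columns for c in ("FID", "IID", "PHENOTYPE"))
    if plink:
        subject_ids = df["IID"].astype(str).tolist()
        y_raw = df["PHENOTYPE"]
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        y = _validate_int_column(y_raw, "PHENOTYPE", {1, 2}, path) - 1
    else:
        if phenotype_column not in df.columns:
            raise ValueError(
                f"{path}: phenotype column {phenotype_column!r} not found"
            )
        subject_ids = [str(i) for i in df.index]
        snp_cols = [c for c in df.columns if c != phenotype_column]
        y = _validate_int_column(df[phenotype_column], phenotype_column, {0, 1}, path)
    if not snp_cols:
        raise ValueError(f"{path}: no SNP columns found")

    genotypes = np.empty((df.shape[0], len(snp_cols)), dtype=np.int64)
    for j, col in enumerate(snp_cols):
        genotypes[:, j] = _validate_int_column(df[col], col, {0, 1, 2}, path)
    return GenotypeMatrix(genotypes, y, [str(c) for c in snp_cols], subject_ids)


def _validate_int_column(series: pd.Series, name: str, allowed: set, path) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() | (vals != vals.round()) | ~vals.isin(list(allowed))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: invalid value {series.iloc[i]!r} in column {name!r}, "
            f"data row {i} (allowed: {sorted(allowed)})"
        )
    return vals.to_numpy().astype(np.int64)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _config_header(seed, config) -> list[str]:
    lines = [f"# seed: {seed}"]
    if config is not None:
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        lines.append(f"# config: {json.dumps(config, default=str)}")
    return lines


def write_table_report(frame: pd.DataFrame, path, seed, config=None) -> None:
    """Write a DataFrame as TSV with seed/config header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _config_header(seed, config):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_fit_report(
    result: FitResult, data: GenotypeMatrix, path, config=None
) -> None:
    """Write a fitted model as a sectioned TSV report.

    Sections: ``[meta]`` (likelihood, convergence, seed, below-threshold
    fractions), ``[links]`` (regime coefficients b1..b4 and threshold c per
    link, with bootstrap sds when present), ``[index]`` (per-SNP alpha/beta
    loadings, with sds), ``[link_curve]`` (g1/g2 on a grid over the observed
    index range, for plotting).  Estimates are written at full precision and
    round-trip exactly through :func:`read_fit_report`.
    """
    t = result.theta_hat
    sd = result.sd
    f1, f2 = below_threshold_fractions(t, data)
    path = Path(path)
    fmt = lambda v: _FLOAT_FMT % v  # noqa: E731

    with open(path, "w") as fh:
        fh.write("# tilor fit report\n")
        for line in _config_header(result.seed, config):
            fh.write(line + "\n")
        fh.write("[meta]\nkey\tvalue\n")
        meta = {
            "n": data.n,
            "n_cases": data.n_cases,
            "n_controls": data.n_controls,
            "p": data.p,
            "loglik": fmt(result.loglik),
            "objective": fmt(result.objective),
            "n_restarts_run": result.n_restarts_run,
            "best_restart_index": result.best_restart_index,
            "converged": result.converged,
            "seed": result.seed,
            "below_threshold_alpha": fmt(f1),
            "below_threshold_beta": fmt(f2),
        }
        for k, v in meta.items():
            fh.write(f"{k}\t{v}\n")

        fh.write("[links]\n")
        cols = ["link", "b1", "b2", "b3", "b4", "c"]
        if sd is not None:
            cols += ["b1_sd", "b2_sd", "b3_sd", "b4_sd", "c_sd"]
        fh.write("\t".join(cols) + "\n")
        for name, link, link_sd in (("g1", t.g1, sd.g1 if sd else None),
                                    ("g2", t.g2, sd.g2 if sd else None)):
            row = [name] + [fmt(v) for v in (link.b1, link.b2, link.b3, link.b4, link.c)]
            if link_sd is not None:
                row += [fmt(v) for v in (link_sd.b1, link_sd.b2, link_sd.b3,
                                         link_sd.b4, link_sd.c)]
            fh.write("\t".join(row) + "\n")

        fh.write("[index]\n")
        cols = ["snp_id", "alpha", "beta"]
        if sd is not None:
            cols += ["alpha_sd", "beta_sd"]
        fh.write("\t".join(cols) + "\n")
        for j, snp in enumerate(data.snp_ids):
            row = [snp, fmt(t.alpha[j]), fmt(t.beta[j])]
            if sd is not None:
                row += [fmt(sd.alpha[j]), fmt(sd.beta[j])]
            fh.write("\t".join(row) + "\n")

        fh.write("[link_curve]\nu_g1\tg1\tu_g2\tg2\n")
        X = np.asarray(data.genotypes, dtype=float)
        from .model import eval_threshold_link

        u1 = X @ t.alpha
        u2 = X @ t.beta
        grid1 = np.linspace(u1.min(), u1.max(), 101)
        grid2 = np.linspace(u2.min(), u2.max(), 101)
        gv1 = eval_threshold_link(t.g1, grid1)
        gv2 = eval_threshold_link(t.g2, grid2)
        for a, b, c, d in zip(grid1, gv1, grid2, gv2):
            fh.write("\t".join(fmt(v) for v in (a, b, c, d)) + "\n")


def read_fit_report(path) -> dict:
    """Re-parse a fit report; returns meta dict, theta (and sd if present)."""
    sections: dict[str, list[list[str]]] = {}
    current = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        sections[current].append(line.split("\t"))

    meta_rows = sections["meta"][1:]
    meta = {k: v for k, v in meta_rows}

    link_header = sections["links"][0]
    links = {}
    links_sd = {}
    has_sd = "b1_sd" in link_header
    for row in sections["links"][1:]:
        rec = dict(zip(link_header, row))
        links[rec["link"]] = ThresholdLinkParams(
            *(float(rec[k]) for k in ("b1", "b2", "b3", "b4", "c"))
        )
        if has_sd:
            links_sd[rec["link"]] = ThresholdLinkParams(
                *(float(rec[k]) for k in ("b1_sd", "b2_sd", "b3_sd", "b4_sd", "c_sd"))
            )

    idx_header = sections["index"][0]
    rows = [dict(zip(idx_header, r)) for r in sections["index"][1:]]
    alpha = np.array([float(r["alpha"]) for r in rows])
    beta = np.array([float(r["beta"]) for r in rows])
    out = {
        "meta": meta,
        "snp_ids": [r["snp_id"] for r in rows],
        "theta": TILoRParams(alpha, beta, links["g1"], links["g2"]),
    }
    if has_sd:
        out["sd"] = TILoRParams(
            np.array([float(r["alpha_sd"]) for r in rows]),
            np.array([float(r["beta_sd"]) for r in rows]),
            links_sd["g1"],
            links_sd["g2"],
        )
    return out
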