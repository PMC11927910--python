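"""Tabular I/O, the two-coin fixture generator, and gambling benchmarks.

Prediction tables are plain delimited text (comma or tab, chosen by file
extension) with a header naming one binary outcome column and one or two
probability columns.  Reports are written back as delimited tables with a
``#``-comment header recording version, seed and configuration so every run
is reproducible from its own output.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CLIP_EPS, ImvResult
from .resampling import FoldReport

__all__ = [
    "VIGORISH_BENCHMARKS",
    "PredictionTable",
    "TwoCoinFixture",
    "read_prediction_table",
    "generate_two_coin_fixture",
    "emit_report",
    "read_report",
]

#: House edges of common games of chance (plus the value of knowing a coin's
#: initial state before a toss), as contextual comparators for IMV values.
#: These are fixed reference constants, not computed quantities.
VIGORISH_BENCHMARKS = {
    "blackjack": 0.010,
    "coin_initial_state": 0.019,
    "baccarat": 0.048,
    "sports_book": 0.091,
}


def _sep_for(path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass(frozen=True)
class PredictionTable:
    y: np.ndarray
    p0: np.ndarray
    p1: np.ndarray | None
    source: str
    dialect: str  # "comma" or "tab"


def read_prediction_table(
    path,
    y_col: str = "y",
    p0_col: str = "p0",
    p1_col: str | None = "p1",
    clip: bool = False,
) -> PredictionTable:
    """Read and validate a delimited prediction table.

    Rows with missing values are rejected with their line numbers; the
    outcome column must be exactly 0/1 and probability columns must be
    interior unless ``clip`` maps saturated values to [1e-12, 1 - 1e-12].
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = [y_col, p0_col] + ([p1_col] if p1_col else [])
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r} (have {list(df.columns)})")
    sub = df[cols]
    bad = sub.index[sub.isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: missing values on line(s) {lines}")

    y = sub[y_col].to_numpy(dtype=float)
    nonbin = np.nonzero(~((y == 0.0) | (y == 1.0)))[0]
    if nonbin.size:
        raise ValueError(
            f"{path}: non-binary outcome value {y[nonbin[0]]!r} on line "
            f"{nonbin[0] + 2}"
        )

    def probs(col):
        p = sub[col].to_numpy(dtype=float)
        if clip:
            p = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
        out = np.nonzero((p <= 0.0) | (p >= 1.0))[0]
        if out.size:
            raise ValueError(
                f"{path}: probability {p[out[0]]!r} outside (0,1) in column "
                f"{col!r} on line {out[0] + 2}; pass clip to accept saturated "
                "values"
            )
        return p

    return PredictionTable(
        y=y,
        p0=probs(p0_col),
        p1=probs(p1_col) if p1_col else None,
        source=str(path),
        dialect="tab" if sep == "\t" else "comma",
    )


@dataclass(frozen=True)
class TwoCoinFixture:
    """Outcomes of a fair-coin block followed by a weighted-coin block,
    with a constant baseline prediction and a blockwise enhanced one."""

    y: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    group: np.ndarray  # 0 = fair block, 1 = weighted block

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"y": self.y.astype(int), "p0": self.p0, "p1": self.p1,
             "group": self.group}
        )


def generate_two_coin_fixture(
    n_fair: int = 20,
    n_weighted: int = 20,
    w_weighted: float = 0.95,
    p0_constant: float = 0.55,
    p1_fair: float = 0.5,
    p1_weighted: float = 0.9,
    seed: int | None = None,
    fixed_counts: tuple[int, int] | None = None,
) -> TwoCoinFixture:
    """Two-coin toy data: a fair block then a heavily weighted block.

    In ``fixed_counts=(heads_fair, heads_weighted)`` mode the realisation is
    deterministic (heads first within each block); ``fixed_counts=(14, 19)``
    regenerates the canonical 33-heads/7-tails dataset.  Otherwise tosses
    are drawn Bernoulli with the given seed.
    """
    if not 0.0 < w_weighted < 1.0:
        raise ValueError("w_weighted must lie in (0, 1)")
    if n_fair < 1 or n_weighted < 1:
        raise ValueError("both blocks need at least one toss")
    if fixed_counts is not None:
        h_fair, h_weighted = fixed_counts
        if not (0 <= h_fair <= n_fair and 0 <= h_weighted <= n_weighted):
            raise ValueError("fixed head counts exceed block sizes")
        y = np.concatenate(
            [
                np.ones(h_fair), np.zeros(n_fair - h_fair),
                np.ones(h_weighted), np.zeros(n_weighted - h_weighted),
            ]
        )
    else:
        if seed is None:
            raise ValueError("seeded mode requires a seed")
        rng = np.random.default_rng(seed)
        y = np.concatenate(
            [
                rng.binomial(1, 0.5, n_fair).astype(float),
                rng.binomial(1, w_weighted, n_weighted).astype(float),
            ]
        )
    n = n_fair + n_weighted
    group = np.concatenate([np.zeros(n_fair, dtype=int), np.ones(n_weighted, dtype=int)])
    p1 = np.where(group == 0, p1_fair, p1_weighted)
    return TwoCoinFixture(y=y, p0=np.full(n, p0_constant), p1=p1, group=group)


def _as_frame(result) -> pd.DataFrame:
    if isinstance(result, ImvResult):
        return pd.DataFrame(
            [
                {
                    "n": result.n, "a0": result.a0, "a1": result.a1,
                    "w0": result.w0, "w1": result.w1, "omega": result.omega,
                }
            ]
        )
    if isinstance(result, FoldReport):
        rows = [
            {"fold": j + 1, "n": int(nj), "omega": om}
            for j, (om, nj) in enumerate(zip(result.omegas, result.n_per_fold))
        ]
        rows.append(
            {"fold": "summary", "n": int(result.n_per_fold.sum()),
             "omega": result.mean_omega}
        )
        return pd.DataFrame(rows)
    if isinstance(result, pd.DataFrame):
        return result
    raise TypeError(f"cannot emit a report for {type(result).__name__}")


def emit_report(result, path, config: dict | None = None) -> None:
    """Write a result as a delimited table with a reproducibility header.

    The header comment block records the package version and any supplied
    config items (seed included) as ``# key=value`` lines; values are kept
    at full double precision so re-reading reproduces them exactly.
    """
    frame = _as_frame(result)
    sep = _sep_for(path)
    buf = _io.StringIO()
    buf.write(f"# imv version={__version__}\n")
    for key, val in (config or {}).items():
        buf.write(f"# {key}={val}\n")
    frame.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_report(path) -> pd.DataFrame:
    """Round-trip companion to :func:`emit_report` (comment lines skipped)."""
    return pd.read_csv(path, sep=_sep_for(path), comment="#")
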