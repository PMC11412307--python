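"""Ensemble-averaged chemical shifts and validation against reference data.

NMR chemical shifts of a disordered protein are ensemble averages, so a
candidate ensemble is judged by averaging per-frame predicted shifts over
its members and comparing the result with a reference (experimental or
converged) shift table, per backbone nucleus (HN, HA, CA, CB, C', N).

The headline comparison is the win fraction: over a grid of ensemble sizes,
the fraction of sizes at which the clustered ensemble strictly beats the
equal-size sequential ensemble on a chosen metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import EnsembleSpec

__all__ = [
    "ATOM_TYPES",
    "ShiftTable",
    "AtomScore",
    "EvaluationReport",
    "read_shift_table",
    "ensemble_average",
    "score_against_reference",
    "compare_ce_se",
    "phospho_delta",
]

ATOM_TYPES = ("HN", "HA", "CA", "CB", "C", "N")

# Predictor-dialect atom-name normalization: amide proton aliases, and the
# glycine HA2/HA3 pair which is averaged into a single HA record.
_ATOM_ALIASES = {"H": "HN", "HN": "HN", "HA": "HA", "CA": "CA", "CB": "CB",
                 "C": "C", "CO": "C", "N": "N"}
_HA_PAIR = {"HA2", "HA3"}


@dataclass
class ShiftTable:
    """Chemical-shift records: (frame?, residue, atom type, shift in ppm).

    ``frame`` is present for per-frame predictor tables and absent (all-NA)
    for reference tables.  (frame, residue, atom) combinations are unique.
    """

    df: pd.DataFrame  # columns: frame (nullable Int64), res_index, res_name, atom, shift_ppm

    def __post_init__(self) -> None:
        required = ["frame", "res_index", "res_name", "atom", "shift_ppm"]
        if list(self.df.columns) != required:
            self.df = self.df.reindex(columns=required)
        self.df = self.df.astype(
            {"frame": "Int64", "res_index": int, "res_name": str,
             "atom": str, "shift_ppm": float}
        ).reset_index(drop=True)
        if not np.all(np.isfinite(self.df["shift_ppm"])):
            raise ValueError("shift table contains non-finite shifts")
        dup = self.df.duplicated(subset=["frame", "res_index", "atom"])
        if dup.any():
            row = self.df[dup].iloc[0]
            raise ValueError(
                f"duplicate shift record (frame={row['frame']}, "
                f"residue={row['res_index']}, atom={row['atom']})"
            )

    @staticmethod
    def from_records(records) -> "ShiftTable":
        """records: iterable of (frame-or-None, res_index, res_name, atom, shift)."""
        df = pd.DataFrame(
            records, columns=["frame", "res_index", "res_name", "atom",
                              "shift_ppm"],
        )
        return ShiftTable(df)

    @property
    def has_frames(self) -> bool:
        return self.df["frame"].notna().any()

    def write_tsv(self, path: str) -> None:
        out = self.df.copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _normalize_atoms(df: pd.DataFrame) -> pd.DataFrame:
    """Map predictor atom names onto the canonical six; average HA2/HA3."""
    df = df.copy()
    names = df["atom"].str.upper()
    is_ha_pair = names.isin(_HA_PAIR)
    df.loc[is_ha_pair, "atom"] = "HA"
    known = df["atom"].str.upper().isin(_ATOM_ALIASES)
    skipped = df.loc[~known, "atom"].unique().tolist()
    if skipped:
        warnings.warn(f"skipping records with unknown atom codes: {skipped}",
                      stacklevel=3)
    df = df[known].copy()
    df["atom"] = df["atom"].str.upper().map(_ATOM_ALIASES)
    group_cols = ["frame", "res_index", "res_name", "atom"]
    df = (df.groupby(group_cols, dropna=False, as_index=False)["shift_ppm"]
            .mean())
    return df.reindex(columns=["frame", "res_index", "res_name", "atom",
                               "shift_ppm"])


def read_shift_table(path: str, dialect: str = "generic_tsv",
                     frame: int | None = None) -> ShiftTable:
    """Read a shift table from disk.

    ``generic_tsv`` expects columns frame, res_index, res_name, atom,
    shift_ppm (frame may be empty for reference tables).  The
    ``sparta_pred_tab`` dialect reads a SPARTA+ pred.tab file (VARS/FORMAT
    header, SHIFT column in ppm); these are single-structure files, so
    ``frame`` assigns the frame index (None for a reference table).
    """
    if dialect == "generic_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = {"res_index", "atom", "shift_ppm"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        if "frame" not in df.columns:
            df["frame"] = pd.NA
        if "res_name" not in df.columns:
            df["res_name"] = "UNK"
    elif dialect == "sparta_pred_tab":
        df = _read_sparta_pred_tab(path)
        df["frame"] = frame if frame is not None else pd.NA
    else:
        raise ValueError(f"unknown dialect: {dialect}")
    df = df.reindex(columns=["frame", "res_index", "res_name", "atom",
                             "shift_ppm"])
    return ShiftTable(_normalize_atoms(df))


def _read_sparta_pred_tab(path: str) -> pd.DataFrame:
    vars_line: list[str] | None = None
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "VARS":
                vars_line = parts[1:]
            elif parts[0] in ("REMARK", "DATA", "FORMAT"):
                continue
            elif vars_line is not None:
                rows.append(parts)
    if vars_line is None or not rows:
        raise ValueError(f"{path}: not a SPARTA+ pred.tab file (no VARS header)")
    table = pd.DataFrame(rows, columns=vars_line)
    for col in ("RESID", "SHIFT"):
        if col not in table.columns:
            raise ValueError(f"{path}: pred.tab lacks required column {col}")
    one_letter_to_three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
    resname = table.get("RESNAME", pd.Series(["X"] * len(table)))
    return pd.DataFrame({
        # SPARTA+ numbers residues from 1; internal indexing is 0-based
        "res_index": table["RESID"].astype(int) - 1,
        "res_name": resname.map(lambda s: one_letter_to_three.get(s, str(s))),
        "atom": table["ATOMNAME"].astype(str),
        "shift_ppm": table["SHIFT"].astype(float),
    })


def ensemble_average(per_frame: ShiftTable, ens: EnsembleSpec,
                     use_weights: bool = False) -> ShiftTable:
    """Average per-frame shifts over the frames of an ensemble.

    Per (residue, atom) the mean is uniform over ensemble frames by default
    or population-weighted with ``use_weights=True``.  A pair missing from
    some frames is averaged over the frames that do carry it (weights
    renormalized); a frame with no records at all is an error.
    """
    df = per_frame.df
    if not per_frame.has_frames:
        raise ValueError("per-frame table required (frame column is empty)")
    frames = ens.frame_indices
    if ens.weights is not None and use_weights:
        w = dict(zip(frames.tolist(), ens.weights.tolist()))
    else:
        w = {int(f): 1.0 / len(frames) for f in frames}
    present = set(df["frame"].dropna().astype(int).unique())
    absent = [int(f) for f in frames if int(f) not in present]
    if absent:
        raise ValueError(f"ensemble frames missing from shift table: {absent}")
    sub = df[df["frame"].isin(frames)].copy()
    sub["w"] = sub["frame"].astype(int).map(w)
    n_frames = len(frames)

    def _agg(group: pd.DataFrame) -> pd.Series:
        wsum = group["w"].sum()
        return pd.Series({
            "res_name": group["res_name"].iloc[0],
            "shift_ppm": float((group["shift_ppm"] * group["w"]).sum() / wsum),
            "coverage": len(group) / n_frames,
        })

    out = (sub.groupby(["res_index", "atom"])
              .apply(_agg, include_groups=False).reset_index())
    if (out["coverage"] < 1.0).any():
        warnings.warn("some (residue, atom) pairs missing in part of the "
                      "ensemble; averaged over available frames", stacklevel=2)
    out["frame"] = pd.NA
    table = ShiftTable(out.reindex(
        columns=["frame", "res_index", "res_name", "atom", "shift_ppm"]))
    return table


@dataclass
class AtomScore:
    r2: float          # squared Pearson correlation (nan if undefined)
    rmse: float        # ppm
    n: int
    r2_defined: bool = True


@dataclass
class EvaluationReport:
    """Per-atom-type agreement between predicted and reference shifts."""

    scores: dict[str, AtomScore]
    provenance: dict = field(default_factory=dict)

    def r2(self, atom: str) -> float:
        return self.scores[atom].r2

    def rmse(self, atom: str) -> float:
        return self.scores[atom].rmse


def score_against_reference(pred: ShiftTable, ref: ShiftTable,
                            drop_proline_N: bool = True) -> EvaluationReport:
    """Score predicted against reference shifts per atom type.

    Pairs are matched on (residue, atom).  r² is the squared Pearson
    correlation and RMSE the root-mean-square difference in ppm, pooled over
    residues within each atom type.  Proline N pairs are excluded by default
    (common predictors do not emit them); a zero-variance reference makes r²
    undefined (flagged) while RMSE is still reported.
    """
    merged = pred.df.merge(
        ref.df, on=["res_index", "atom"], suffixes=("_pred", "_ref"))
    if drop_proline_N:
        is_pro_n = (merged["atom"] == "N") & (
            merged["res_name_ref"].str.upper().eq("PRO")
            | merged["res_name_pred"].str.upper().eq("PRO"))
        merged = merged[~is_pro_n]
    if merged.empty:
        raise ValueError("no common (residue, atom) pairs to score")
    scores: dict[str, AtomScore] = {}
    for atom, grp in merged.groupby("atom"):
        if len(grp) < 2:
            continue
        x = grp["shift_ppm_pred"].to_numpy()
        y = grp["shift_ppm_ref"].to_numpy()
        rmse = float(np.sqrt(np.mean((x - y) ** 2)))
        if np.std(x) == 0 or np.std(y) == 0:
            scores[atom] = AtomScore(np.nan, rmse, len(grp), r2_defined=False)
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            scores[atom] = AtomScore(r * r, rmse, len(grp))
    if not scores:
        raise ValueError("no atom type has >= 2 common pairs")
    return EvaluationReport(scores)


def compare_ce_se(ce_scores: dict[int, EvaluationReport],
                  se_scores: dict[int, EvaluationReport],
                  metric: str = "r2", atom: str = "HN") -> float:
    """Fraction of ensemble sizes where CE strictly beats SE.

    ``metric`` is ``r2`` (higher wins) or ``rmse`` (lower wins); ties count
    as non-wins so the headline fraction is never inflated.
    """
    if sorted(ce_scores) != sorted(se_scores):
        raise ValueError("CE and SE were scored on different k grids")
    if metric not in ("r2", "rmse"):
        raise ValueError("metric must be 'r2' or 'rmse'")
    wins = 0
    ks = sorted(ce_scores)
    for k in ks:
        ce = getattr(ce_scores[k], metric)(atom)
        se = getattr(se_scores[k], metric)(atom)
        if metric == "r2":
            wins += bool(np.isfinite(ce) and np.isfinite(se) and ce > se)
        else:
            wins += bool(ce < se)
    return wins / len(ks)


def phospho_delta(shifted: ShiftTable, unshifted: ShiftTable,
                  atom: str = "HN",
                  threshold: float | None = None) -> pd.DataFrame:
    """Per-residue shift perturbation Δδ = δ_phospho − δ_nonphospho.

    Residues are matched by index (the phosphorylated table uses
    SEP/TPO/PTR codes at the modified positions).  Classification:
    ``deshielded`` (downfield) if Δδ > threshold, ``shielded`` (upfield) if
    Δδ < −threshold, else ``unchanged``.  Default thresholds: 0.05 ppm for
    ¹H nuclei, 0.2 ppm for heavy nuclei.
    """
    if threshold is None:
        threshold = 0.05 if atom in ("HN", "HA") else 0.2
    a = shifted.df[shifted.df["atom"] == atom]
    b = unshifted.df[unshifted.df["atom"] == atom]
    merged = a.merge(b, on="res_index", suffixes=("_p", "_u"))
    only = set(a["res_index"]) ^ set(b["res_index"])
    if only:
        warnings.warn(f"residues present in only one table skipped: "
                      f"{sorted(only)}", stacklevel=2)
    delta = merged["shift_ppm_p"] - merged["shift_ppm_u"]
    klass = np.where(delta > threshold, "deshielded",
                     np.where(delta < -threshold, "shielded", "unchanged"))
    return pd.DataFrame({
        "res_index": merged["res_index"],
        "res_name": merged["res_name_p"],
        "atom": atom,
        "delta_ppm": delta,
        "classification": klass,
    }).sort_values("res_index").reset_index(drop=True)
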