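"""Study-level evaluation: the model object tying the pipeline together.

:class:`LvhScreeningStudy` is built from a cohort table (one row per subject:
gold-standard LVH label plus the binary outcome of each ECG criterion) and,
optionally, a re-read table. Its :meth:`~LvhScreeningStudy.fit` computes

* a descriptive table (counts and percentages of the cohort),
* diagnostic test characteristics per criterion (with sex-restricted Cornell
  rows) against the gold standard,
* paired non-inferiority tests of the reference sign against every other
  criterion, on both the sensitivity endpoint (correct classification among
  gold-positives) and the specificity endpoint (among gold-negatives),
* Cohen's kappa per criterion when re-read data are supplied,

and returns them as a :class:`LvhScreeningResults` with a ``summary()`` text
report and deterministic TSV/JSON writers. Reports echo the full
configuration and its hash so that a run is reproducible byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy, paired
from .criteria import CriteriaThresholds
from .waveform import LayoutGeometry
from ._util import round_half_up

__all__ = ["RunConfig", "LvhScreeningStudy", "LvhScreeningResults"]

DEFAULT_CRITERIA = ("seamens", "sl1", "sl2", "cornell")

CRITERION_LABELS = {
    "seamens": "Seamens' Sign",
    "sl1": "Sokolow-Lyon 1",
    "sl2": "Sokolow-Lyon 2",
    "cornell": "Cornell Overall",
    "cornell_men": "Cornell Men",
    "cornell_women": "Cornell Women",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable run configuration, echoed into every report."""

    geometry: LayoutGeometry = field(default_factory=LayoutGeometry)
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    ci_method: str = "wilson"
    conf: float = 0.95
    delta: float = 0.05
    alpha: float = 0.05
    endpoints: Sequence[str] = ("sensitivity", "specificity")
    rounding_decimals: int = 2
    summary_method: str = "median"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "thresholds": self.thresholds.to_dict(),
            "ci_method": self.ci_method,
            "conf": self.conf,
            "delta": self.delta,
            "alpha": self.alpha,
            "endpoints": list(self.endpoints),
            "rounding_decimals": self.rounding_decimals,
            "summary_method": self.summary_method,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = LayoutGeometry.from_dict(d["geometry"])
        if "thresholds" in d:
            d["thresholds"] = CriteriaThresholds(**d["thresholds"])
        if "endpoints" in d:
            d["endpoints"] = tuple(d["endpoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _validate_cohort(cohort: pd.DataFrame, criteria: Sequence[str],
                     gold_col: str, sex_col: str) -> None:
    missing = [c for c in (gold_col, *criteria) if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required column(s): {missing}")
    for col in (gold_col, *criteria):
        vals = pd.unique(cohort[col].dropna())
        bad = [v for v in vals if v not in (0, 1, True, False)]
        if bad:
            rows = cohort.index[~cohort[col].isin((0, 1))].tolist()[:5]
            raise ValueError(
                f"column {col!r} must be binary 0/1; offending values {bad} "
                f"at row index(es) {rows}")


class LvhScreeningStudy:
    """Evaluation of ECG-LVH screening criteria against a gold standard.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with a binary ``gold`` column and one binary
        column per criterion.
    criteria : sequence of str
        Criterion columns to evaluate (default: the four study criteria
        present in the table).
    reference : str
        The criterion whose non-inferiority against every other is tested
        (default ``'seamens'``).
    reread : DataFrame, optional
        Long-format re-read table ``subject_id, criterion, read1, read2``
        for inter-rater agreement.
    config : RunConfig
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        criteria: Optional[Sequence[str]] = None,
        reference: str = "seamens",
        gold_col: str = "gold",
        sex_col: str = "sex",
        reread: Optional[pd.DataFrame] = None,
        config: Optional[RunConfig] = None,
    ):
        if criteria is None:
            criteria = [c for c in DEFAULT_CRITERIA if c in cohort.columns]
            if not criteria:
                raise ValueError("no criterion columns found in cohort table")
        _validate_cohort(cohort, criteria, gold_col, sex_col)
        if reference not in criteria:
            raise ValueError(f"reference criterion {reference!r} not among "
                             f"criteria {list(criteria)}")
        self.cohort = cohort.reset_index(drop=True)
        self.criteria = list(criteria)
        self.reference = reference
        self.gold_col = gold_col
        self.sex_col = sex_col
        self.reread = reread
        self.config = config or RunConfig()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_csv(cls, cohort_path, reread_path=None, **kwargs) -> "LvhScreeningStudy":
        cohort = pd.read_csv(cohort_path)
        reread = pd.read_csv(reread_path) if reread_path else None
        return cls(cohort, reread=reread, **kwargs)

    @classmethod
    def from_simulation(cls, cohort_spec=None, reread_flip_prob: float = 0.02,
                        **kwargs) -> "LvhScreeningStudy":
        """Build the study from :func:`lvhscreen.synthetic.simulate_cohort`."""
        from .synthetic import CohortSpec, simulate_cohort, simulate_reread

        spec = cohort_spec or CohortSpec()
        cohort = simulate_cohort(spec)
        rereads = [
            simulate_reread(cohort, crit, reread_flip_prob, seed=spec.seed + 1 + i)
            for i, crit in enumerate(c for c in DEFAULT_CRITERIA
                                     if c in cohort.columns)
        ]
        reread = pd.concat(rereads, ignore_index=True)
        return cls(cohort, reread=reread, **kwargs)

    # -- helpers -----------------------------------------------------------
    def _rows(self) -> List[tuple]:
        """(key, label, subset mask, criterion column) incl. sex-restricted Cornell."""
        rows = [(c, CRITERION_LABELS.get(c, c), None, c) for c in self.criteria]
        if "cornell" in self.criteria and self.sex_col in self.cohort.columns:
            sexes = self.cohort[self.sex_col].astype(str).str.upper().str[:1]
            rows.append(("cornell_men", CRITERION_LABELS["cornell_men"],
                         (sexes == "M").to_numpy(), "cornell"))
            rows.append(("cornell_women", CRITERION_LABELS["cornell_women"],
                         (sexes == "F").to_numpy(), "cornell"))
        return rows

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "LvhScreeningResults":
        cfg = self.config
        gold = self.cohort[self.gold_col].to_numpy(dtype=int)

        descriptive = self._descriptive_table()
        characteristics = self._characteristics_table(gold, cfg)
        noninferiority = self._noninferiority_table(gold, cfg)
        agreement = self._agreement_table(cfg) if self.reread is not None else None
        return LvhScreeningResults(
            model=self,
            descriptive=descriptive,
            characteristics=characteristics,
            noninferiority=noninferiority,
            agreement=agreement,
            config=cfg,
        )

    def _descriptive_table(self) -> pd.DataFrame:
        df = self.cohort
        n = len(df)
        rows = []

        def pct_row(variable, level, count, denom):
            rows.append({
                "variable": variable, "level": level, "n": denom,
                "count": count,
                "percent": round_half_up(100.0 * count / denom) if denom else np.nan,
                "median": np.nan, "q1": np.nan, "q3": np.nan,
            })

        def num_row(variable, series):
            s = pd.to_numeric(series, errors="coerce").dropna()
            rows.append({
                "variable": variable, "level": "", "n": int(s.size),
                "count": np.nan, "percent": np.nan,
                "median": float(s.median()), "q1": float(s.quantile(0.25)),
                "q3": float(s.quantile(0.75)),
            })

        if "age" in df.columns:
            num_row("age", df["age"])
        if self.sex_col in df.columns:
            sexes = df[self.sex_col].astype(str).str.upper().str[:1]
            pct_row("sex", "male", int((sexes == "M").sum()), n)
            pct_row("sex", "female", int((sexes == "F").sum()), n)
        gold = df[self.gold_col].astype(int)
        pct_row("gold (TTE LVH)", "no", int((gold == 0).sum()), n)
        pct_row("gold (TTE LVH)", "yes", int((gold == 1).sum()), n)
        if "ecg_to_tte_days" in df.columns:
            num_row("ecg_to_tte_days", df["ecg_to_tte_days"])
        for key, label, mask, col in self._rows():
            sub = df if mask is None else df.loc[mask]
            denom = len(sub)
            pos = int(sub[col].astype(int).sum())
            pct_row(f"{label} positive", "no", denom - pos, denom)
            pct_row(f"{label} positive", "yes", pos, denom)
        return pd.DataFrame(rows, columns=["variable", "level", "n", "count",
                                           "percent", "median", "q1", "q3"])

    def _characteristics_table(self, gold, cfg) -> pd.DataFrame:
        rows = []
        for key, label, mask, col in self._rows():
            pred = self.cohort[col].to_numpy(dtype=int)
            g, p = (gold, pred) if mask is None else (gold[mask], pred[mask])
            counts = accuracy.ConfusionCounts.from_labels(g, p)
            ch = accuracy.test_characteristics(counts, ci_method=cfg.ci_method,
                                               conf=cfg.conf)
            row = {"criterion": key, "label": label, "n": counts.n,
                   "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                   "tn": counts.tn}
            for qty in ("sensitivity", "specificity", "ppv", "npv"):
                est = getattr(ch, qty)
                row[qty] = est.value
                row[f"{qty}_lo"] = est.lo
                row[f"{qty}_hi"] = est.hi
                row[f"{qty}_defined"] = est.defined
            rows.append(row)
        return pd.DataFrame(rows)

    def _noninferiority_table(self, gold, cfg) -> pd.DataFrame:
        ref = self.cohort[self.reference].to_numpy(dtype=int)
        rows = []
        for key, label, mask, col in self._rows():
            if key == self.reference:
                continue
            comp = self.cohort[col].to_numpy(dtype=int)
            for endpoint in cfg.endpoints:
                if endpoint == "sensitivity":
                    strat = gold == 1
                    a, b = ref, comp
                elif endpoint == "specificity":
                    strat = gold == 0
                    a, b = 1 - ref, 1 - comp
                elif endpoint == "accuracy":
                    strat = np.ones_like(gold, dtype=bool)
                    a, b = (ref == gold).astype(int), (comp == gold).astype(int)
                else:
                    raise ValueError(f"unknown endpoint {endpoint!r}")
                if mask is not None:
                    strat = strat & mask
                if not strat.any():
                    continue
                table = paired.PairedBinaryTable.from_labels(a[strat], b[strat])
                res = paired.paired_noninferiority(table, delta=cfg.delta,
                                                   alpha=cfg.alpha,
                                                   endpoint=endpoint)
                rows.append({
                    "comparison": key, "label": label, "endpoint": endpoint,
                    "n": res.n, "n10": res.n10, "n01": res.n01,
                    "difference": res.difference, "delta": res.delta,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "non_inferior": res.non_inferior,
                })
        return pd.DataFrame(rows)

    def _agreement_table(self, cfg) -> pd.DataFrame:
        req = {"criterion", "read1", "read2"}
        if not req.issubset(self.reread.columns):
            raise ValueError(f"re-read table must contain columns {sorted(req)}")
        rows = []
        for crit, grp in self.reread.groupby("criterion", sort=False):
            table = paired.agreement_table_from_reads(
                grp["read1"].astype(int), grp["read2"].astype(int))
            res = paired.cohen_kappa(table, conf=cfg.conf)
            rows.append({
                "criterion": crit,
                "label": CRITERION_LABELS.get(crit, crit),
                "n": res.n, "kappa": res.kappa, "lo": res.lo, "hi": res.hi,
                "po": res.po, "pe": res.pe, "defined": res.defined,
            })
        return pd.DataFrame(rows)


@dataclass
class LvhScreeningResults:
    """Fit results: descriptive, accuracy, non-inferiority and agreement tables."""

    model: LvhScreeningStudy
    descriptive: pd.DataFrame
    characteristics: pd.DataFrame
    noninferiority: pd.DataFrame
    agreement: Optional[pd.DataFrame]
    config: RunConfig

    @property
    def config_hash(self) -> str:
        return self.config.hash

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        dec = cfg.rounding_decimals
        lines = []
        lines.append("LVH screening criteria evaluation")
        lines.append("=" * 70)
        lines.append(f"subjects: {len(self.model.cohort)}   "
                     f"reference: {CRITERION_LABELS.get(self.model.reference, self.model.reference)}")
        lines.append(f"CI method: {cfg.ci_method} ({cfg.conf:.0%})   "
                     f"NI margin delta: {cfg.delta}   one-sided alpha: {cfg.alpha}")
        lines.append(f"geometry: gain {cfg.geometry.gain} mm/mV, "
                     f"speed {cfg.geometry.paper_speed} mm/s, "
                     f"baseline separation {cfg.geometry.baseline_separation} mm")
        lines.append(f"config hash: {self.config_hash}")
        lines.append("")
        lines.append("Cohort description")
        lines.append("-" * 70)
        for _, r in self.descriptive.iterrows():
            if pd.notna(r["percent"]):
                lines.append(f"  {r['variable']:<34} {str(r['level']):<8} "
                             f"{int(r['percent']):>3d}% ({int(r['count'])})")
            else:
                lines.append(f"  {r['variable']:<34} {'':<8} "
                             f"{r['median']:g} ({r['q1']:g}, {r['q3']:g})")
        lines.append("")
        lines.append("Test characteristics vs gold standard")
        lines.append("-" * 70)
        head = f"  {'criterion':<16}" + "".join(
            f"{q:>22}" for q in ("sens (95% CI)", "spec (95% CI)",
                                 "PPV (95% CI)", "NPV (95% CI)"))
        lines.append(head)
        for _, r in self.characteristics.iterrows():
            cells = []
            for qty in ("sensitivity", "specificity", "ppv", "npv"):
                if r[f"{qty}_defined"]:
                    cells.append(f"{r[qty]:.{dec}f} "
                                 f"({r[f'{qty}_lo']:.{dec}f}-{r[f'{qty}_hi']:.{dec}f})")
                else:
                    cells.append("undefined")
            lines.append(f"  {r['label']:<16}" + "".join(f"{c:>22}" for c in cells))
        lines.append("")
        ref_label = CRITERION_LABELS.get(self.model.reference, self.model.reference)
        lines.append(f"Non-inferiority of {ref_label} (margin {cfg.delta}, one-sided)")
        lines.append("-" * 70)
        lines.append(f"  {'comparison':<16}{'endpoint':<14}{'diff':>8}"
                     f"{'z':>8}{'p':>10}{'non-inferior':>14}")
        for _, r in self.noninferiority.iterrows():
            p_txt = "<0.001" if r["p_value"] < 0.001 else f"{r['p_value']:.3f}"
            lines.append(f"  {r['label']:<16}{r['endpoint']:<14}"
                         f"{r['difference']:>8.3f}{r['statistic']:>8.2f}"
                         f"{p_txt:>10}{str(bool(r['non_inferior'])):>14}")
        if self.agreement is not None and len(self.agreement):
            lines.append("")
            lines.append("Inter-rater agreement (Cohen's kappa)")
            lines.append("-" * 70)
            for _, r in self.agreement.iterrows():
                if r["defined"]:
                    lines.append(f"  {r['label']:<16} kappa {r['kappa']:.2f} "
                                 f"({r['lo']:.2f}-{r['hi']:.2f})  n={int(r['n'])}")
                else:
                    lines.append(f"  {r['label']:<16} kappa undefined  n={int(r['n'])}")
        lines.append("")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def records(df):
            if df is None:
                return None
            return json.loads(df.to_json(orient="records"))

        return {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "n_subjects": len(self.model.cohort),
            "reference": self.model.reference,
            "descriptive": records(self.descriptive),
            "characteristics": records(self.characteristics),
            "noninferiority": records(self.noninferiority),
            "agreement": records(self.agreement),
        }

    def save(self, outdir) -> Dict[str, Path]:
        """Write TSV tables plus a machine-readable JSON bundle.

        Output is deterministic: fixed row order, fixed float formatting and
        the config hash embedded in every file.
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def write_tsv(df, name):
            path = out / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# lvhscreen report; config_hash={self.config_hash}\n")
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            paths[name] = path

        write_tsv(self.descriptive, "descriptive")
        write_tsv(self.characteristics, "characteristics")
        write_tsv(self.noninferiority, "noninferiority")
        if self.agreement is not None:
            write_tsv(self.agreement, "agreement")
        bundle = out / "report.json"
        with open(bundle, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        paths["report"] = bundle
        summary_path = out / "summary.txt"
        summary_path.write_text(self.summary())
        paths["summary"] = summary_path
        return paths
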