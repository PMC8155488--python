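"""Virtual drug-trial pipeline: ensembles, deltas, statistics, termination.

A trial runs a grid of cases — substrate replicate x genotype x (baseline +
drug x dose) — computes per-case wave metrics, pairs every drug case with
its own baseline (same substrate, same genotype) for delta statistics, and
summarizes termination rates by drug, dose, class and genotype.

Statistical conventions: two-sample comparisons use Student's t (equal
variance), dose comparisons within a model use the paired t-test, effect
sizes are Cohen's d with pooled (n−1-weighted) SD, and termination-rate
contrasts use Fisher's exact test on the 2x2 counts.  No multiple-testing
correction is applied.  Cases that terminate before the start of the
analysis window are excluded from wave-dynamic summaries but always appear
in the termination tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cellmodel, conditions, substrate as substrate_mod, tissue, wavedyn
from .cellmodel import ConductanceScales
from .conditions import Condition, DrugBlockTable

__all__ = [
    "TrialDesign",
    "TrialReport",
    "cohens_d",
    "termination_rates_from_counts",
    "two_sample_t",
    "paired_t",
    "fisher_exact_2x2",
    "termination_table",
    "run_trial",
    "run_single_case",
    "case_seed",
]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d: |mean difference| / pooled SD (n−1 weighting).

    Returns NaN (undefined flag) when the pooled SD is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
        / (na + nb - 2)
    if pooled_var == 0:
        return math.nan
    return float(abs(a.mean() - b.mean()) / math.sqrt(pooled_var))


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Equal-variance two-sample Student's t; returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(res.statistic):
        return math.nan, math.nan     # degenerate variance, flagged as NaN
    return float(res.statistic), float(res.pvalue)


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Paired t-test; returns (t, two-sided p)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if len(before) < 2:
        raise ValueError("need n >= 2 pairs")
    res = stats.ttest_rel(before, after)
    if not np.isfinite(res.statistic):
        return math.nan, math.nan
    return float(res.statistic), float(res.pvalue)


def termination_rates_from_counts(
    counts: dict[str, tuple[int, int]],
) -> dict[str, float]:
    """Plain percentage arithmetic on aggregated (terminated, total) counts.

    Used to reproduce published summary rows directly from their printed
    counts, independent of the per-case pipeline.
    """
    out = {}
    for label, (k, n) in counts.items():
        if not (0 <= k <= n) or n <= 0:
            raise ValueError(f"bad counts for {label}: {k}/{n}")
        out[label] = 100.0 * k / n
    return out


def fisher_exact_2x2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for rates k1/n1 vs k2/n2."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Termination tables
# ---------------------------------------------------------------------------

def termination_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Termination rates by drug/dose, class and genotype, with exact tests.

    ``cases`` needs columns genotype, drug, dose, drug_class, terminated
    (bool); one row per drug case.  Returns a table with counts,
    denominators and percentages per group (overall and per genotype), plus
    Fisher-exact p-values for the class IC vs III and wild-type vs
    deficient contrasts.  Percentages are plain count arithmetic.
    """
    drugged = cases[cases["drug"] != "none"]
    if drugged.empty:
        raise ValueError("no drug cases to tabulate")
    rows = []

    def rate_row(label: str, sel: pd.DataFrame) -> dict:
        row: dict = {"group": label}
        for gname, gsel in [("overall", sel),
                            ("wild_type", sel[sel["genotype"] == "wild_type"]),
                            ("pitx2_deficient",
                             sel[sel["genotype"] == "pitx2_deficient"])]:
            n = len(gsel)
            k = int(gsel["terminated"].sum())
            row[f"{gname}_n"] = n
            row[f"{gname}_terminated"] = k
            row[f"{gname}_pct"] = 100.0 * k / n if n else math.nan
        return row

    rows.append(rate_row("all_aads", drugged))
    for klass in ("IC", "III"):
        rows.append(rate_row(f"class_{klass}",
                             drugged[drugged["drug_class"] == klass]))
    for drug in sorted(drugged["drug"].unique()):
        for dose in ("low", "high"):
            sel = drugged[(drugged["drug"] == drug) & (drugged["dose"] == dose)]
            if len(sel):
                rows.append(rate_row(f"{drug}_{dose}", sel))
    out = pd.DataFrame(rows).set_index("group")

    def counts(sel):
        return int(sel["terminated"].sum()), len(sel)

    ic, iii = (drugged[drugged["drug_class"] == c] for c in ("IC", "III"))
    pvals = {}
    if len(ic) and len(iii):
        pvals["class_IC_vs_III"] = fisher_exact_2x2(*counts(ic), *counts(iii))
    for klass, sel in [("IC", ic), ("III", iii), ("all", drugged)]:
        wt = sel[sel["genotype"] == "wild_type"]
        px = sel[sel["genotype"] == "pitx2_deficient"]
        if len(wt) and len(px):
            pvals[f"{klass}_wt_vs_pitx2"] = fisher_exact_2x2(*counts(wt), *counts(px))
    out.attrs["p_values"] = pvals
    return out


# ---------------------------------------------------------------------------
# Trial design and execution
# ---------------------------------------------------------------------------

@dataclass
class TrialDesign:
    """Everything defining a trial: replicates, conditions and scale choices.

    The default sizes are the package's desk-scale profile; the
    ``--full-scale`` CLI flag switches to the full-study sizes (25 replicates,
    32-s termination window).
    """

    substrate_seeds: tuple[int, ...] = tuple(range(10))
    genotypes: tuple[str, ...] = ("wild_type", "pitx2_deficient")
    drugs: tuple[str, ...] = ("amiodarone", "sotalol", "dronedarone",
                              "flecainide", "propafenone")
    doses: tuple[str, ...] = ("low", "high")
    include_baseline: bool = True
    af_window_s: float = 8.0            # AF analysis/termination window
    size_mm: float = 50.0
    spacing: float = 0.5
    low_voltage_fraction: float = 0.2
    correlation_length: float = 8.0
    anisotropy: float = 1.5
    target_cv: float = 0.30             # plane-wave calibration target, m/s
    d_long: float | None = None         # skip calibration when given
    #: DF band (Hz).  Desk-scale rotors cycle at 2.5-4.5 Hz, so the band
    #: must reach below the clinical 3 Hz edge or the periodogram peak
    #: lands on a harmonic of an out-of-band fundamental.
    df_band: tuple[float, float] = (1.5, 15.0)
    dt: float = 0.05
    record_dt: float = 1.0
    scaled_down: bool = True            # flags desk-scale shortcuts in outputs

    def cases(self) -> list[dict]:
        """Enumerate the full case grid (one dict per case)."""
        out = []
        for seed in self.substrate_seeds:
            for g in self.genotypes:
                combos: list[tuple[str, str | None]] = []
                if self.include_baseline:
                    combos.append(("none", None))
                combos += [(d, dose) for d in self.drugs for dose in self.doses]
                for drug, dose in combos:
                    out.append({"seed": seed, "genotype": g,
                                "drug": drug, "dose": dose})
        return out


def case_seed(master_seed: int, index: int) -> int:
    """Counter-based per-case seed expansion (stable, recorded in manifests)."""
    return int((master_seed * 100003 + 7919 * index + 1) % (2**31 - 1))


@dataclass
class TrialReport:
    """Per-case metric table plus group summaries and tests."""

    cases: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    termination: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cases.to_csv(out / "cases.csv", index=False)
        if "ephys" in self.summaries:
            self.summaries["ephys"].to_csv(out / "table3_ephys.csv")
        if "deltas" in self.summaries:
            self.summaries["deltas"].to_csv(out / "table4_deltas.csv")
        self.termination.to_csv(out / "table5_termination.csv")
        meta = dict(self.manifest)
        meta["termination_p_values"] = self.termination.attrs.get("p_values", {})
        (out / "manifest.json").write_text(json.dumps(meta, indent=2,
                                                      default=str))


def build_trial_substrate(
    design: TrialDesign, master_seed: int, seed_index: int,
    d_long: float,
) -> substrate_mod.Substrate:
    """One replicate substrate of a trial, from its design and seed index."""
    sub = substrate_mod.build_substrate(
        seed=case_seed(master_seed, seed_index),
        size_mm=design.size_mm, spacing=design.spacing,
        correlation_length=design.correlation_length,
        low_voltage_fraction=design.low_voltage_fraction,
        anisotropy=design.anisotropy, d_long=d_long)
    sub.manifest["seed"] = seed_index
    return sub


def screen_inducible_substrates(
    design: TrialDesign,
    master_seed: int,
    n_needed: int = 2,
    max_candidates: int = 4,
    drug_table: DrugBlockTable | None = None,
) -> tuple[list[int], dict]:
    """Baseline inducibility screen: keep substrates that sustain AF.

    Small sheets do not all sustain reentry (as not every atrium is
    inducible); wave-dynamic comparisons need substrates whose drug-free AF
    outlasts the analysis window in *both* genotypes.  Candidate seed
    indices are tried in order until ``n_needed`` qualify or
    ``max_candidates`` have been run.  Returns the qualifying seed indices
    and every baseline case row computed along the way (keyed by
    (seed_index, genotype)), so screening work is never repeated.
    """
    if design.d_long is not None:
        d_cal = design.d_long
    else:
        wt_sr = conditions.genotype_baseline("wild_type", "SR")
        d_cal, _ = substrate_mod.calibrate_diffusion(
            wt_sr, target_cv=design.target_cv,
            spacing=design.spacing, dt=design.dt)
    kept: list[int] = []
    rows: dict = {"d_long": d_cal}
    for idx in range(max_candidates):
        sub = build_trial_substrate(design, master_seed, idx, d_cal)
        ok = True
        for g in design.genotypes:
            cond = Condition(g, "AF")
            try:
                row = run_single_case(sub, cond, design, drug_table)
            except Exception as e:
                row = {"status": f"failed: {e}", "terminated": True,
                       "mean_afcl": math.nan}
            rows[(idx, g)] = row
            if row.get("terminated", True) or not np.isfinite(
                    row.get("mean_afcl", math.nan)):
                ok = False
        rows[("substrate", idx)] = sub
        if ok:
            kept.append(idx)
            if len(kept) >= n_needed:
                break
    return kept, rows


def run_single_case(
    sub: substrate_mod.Substrate,
    cond: Condition,
    design: TrialDesign,
    drug_table: DrugBlockTable | None = None,
    run_af: bool = True,
) -> dict:
    """All metrics for one condition on one substrate.

    APD90 uses the sinus-rhythm parameterization paced at CL 600 ms; CV
    the SR parameterization on a plane-wave strand at the substrate's
    diffusion coefficient; Smax a restitution ramp under the AF
    parameterization; AFCL/DF/PS/termination come from the 2D AF run.
    """
    sr_cond = Condition(cond.genotype, "SR", cond.drug, cond.dose)
    af_cond = Condition(cond.genotype, "AF", cond.drug, cond.dose)
    sr_scales = conditions.resolve_condition(sr_cond, drug_table)
    af_scales = conditions.resolve_condition(af_cond, drug_table)

    metrics = wavedyn.WaveMetrics()
    tr = cellmodel.pace_cell(sr_scales, 600.0, n_beats=10)
    metrics.apd90 = cellmodel.measure_apd90(*tr.last_beat())
    metrics.cv = tissue.plane_wave_cv(sub.d_long, sr_scales,
                                      spacing=sub.geometry.spacing)
    try:
        samples = cellmodel.restitution_protocol(af_scales)
        metrics.mean_smax = cellmodel.fit_restitution(samples).smax
    except RuntimeError:
        metrics.mean_smax = math.nan

    charge_series = None
    if run_af:
        af_ms = design.af_window_s * 1000.0
        case = tissue.run_case(sub, sr_scales, af_scales,
                               af_duration=af_ms, dt=design.dt,
                               record_dt=design.record_dt, run_sr=False)
        trace = case.af_trace
        metrics.terminated = case.termination_time is not None
        metrics.termination_time = case.termination_time
        t0 = trace.induction_end + 500.0
        t1 = trace.t[-1]
        if case.termination_time is not None:
            t1 = min(t1, case.termination_time)
        cond_mask = sub.conducting
        if t1 - t0 >= 2000.0:
            metrics.mean_afcl = wavedyn.afcl(trace, t0, t1,
                                             conducting=cond_mask)
            _, metrics.peak_df, metrics.mean_df = wavedyn.dominant_frequency(
                trace, t0, t1, band=design.df_band, conducting=cond_mask)
            n_ps, life, charge = wavedyn.ps_analysis(
                trace, t0, min(t1, t0 + 2000.0), sub.geometry.spacing)
            metrics.ps_number = n_ps
            metrics.ps_lifespan = life
            charge_series = charge.tolist()
    metrics.validate()
    row = metrics.as_dict()
    if charge_series is not None:
        row["ps_total_charge_series"] = charge_series
    row.update({"genotype": cond.genotype, "drug": cond.drug,
                "dose": cond.dose, "drug_class": cond.drug_class,
                "seed": sub.manifest.get("seed"),
                "scales": af_scales.as_dict()})
    return row


METRIC_FIELDS = ("apd90", "cv", "mean_smax", "mean_afcl",
                 "peak_df", "mean_df", "ps_number", "ps_lifespan")


def summarize(cases: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group means ± SD and paired deltas versus matched baselines.

    Wave-dynamic fields of cases that terminated before the analysis
    window are NaN already (excluded); APD90/CV/Smax are always defined.
    """
    df = cases.copy()
    rows = []
    for (g, drugged), sel in df.groupby(["genotype", df["drug"] != "none"]):
        label = f"{g}/{'AAD' if drugged else 'baseline'}"
        for f in METRIC_FIELDS:
            vals = sel[f].dropna()
            rows.append({"group": label, "metric": f, "n": len(vals),
                         "mean": vals.mean(), "sd": vals.std(ddof=1)})
    ephys = pd.DataFrame(rows).set_index(["group", "metric"])

    base = df[df["drug"] == "none"].set_index(["seed", "genotype"])
    drugged = df[df["drug"] != "none"]
    deltas = []
    for _, row in drugged.iterrows():
        key = (row["seed"], row["genotype"])
        if key not in base.index:
            continue
        b = base.loc[key]
        rec = {"seed": row["seed"], "genotype": row["genotype"],
               "drug": row["drug"], "dose": row["dose"],
               "drug_class": row["drug_class"]}
        for f in METRIC_FIELDS:
            rec[f"delta_{f}"] = row[f] - b[f]
        deltas.append(rec)
    deltas_df = pd.DataFrame(deltas)
    return {"ephys": ephys, "deltas": deltas_df}


def run_trial(
    design: TrialDesign,
    master_seed: int = 0,
    drug_table: DrugBlockTable | None = None,
    out_dir: str | Path | None = None,
    run_af: bool = True,
    progress: bool = False,
) -> TrialReport:
    """Run the full case grid and assemble the trial report.

    Substrates are built and diffusion-calibrated once per replicate seed;
    cases are independent given their substrate (embarrassingly parallel in
    principle; run serially here).  With ``out_dir`` set, per-case rows are
    checkpointed as JSON and finished cases are skipped on rerun, and the
    report is regenerated deterministically from the archive.
    """
    drug_table = drug_table or conditions.default_drug_table()
    archive = Path(out_dir) / "cases" if out_dir else None
    if archive:
        archive.mkdir(parents=True, exist_ok=True)

    subs: dict[int, substrate_mod.Substrate] = {}
    d_cal: float | None = None
    rows = []
    all_cases = design.cases()
    for i, c in enumerate(all_cases):
        tag = f"{c['seed']}_{c['genotype']}_{c['drug']}_{c['dose']}"
        ckpt = archive / f"case_{tag}.json" if archive else None
        if ckpt and ckpt.exists():
            rows.append(json.loads(ckpt.read_text()))
            continue
        if c["seed"] not in subs:
            if d_cal is None:
                if design.d_long is not None:
                    d_cal = design.d_long
                else:
                    wt_sr = conditions.genotype_baseline("wild_type", "SR")
                    d_cal, _ = substrate_mod.calibrate_diffusion(
                        wt_sr, target_cv=design.target_cv,
                        spacing=design.spacing, dt=design.dt)
            subs[c["seed"]] = substrate_mod.build_substrate(
                seed=case_seed(master_seed, c["seed"]),
                size_mm=design.size_mm, spacing=design.spacing,
                correlation_length=design.correlation_length,
                low_voltage_fraction=design.low_voltage_fraction,
                anisotropy=design.anisotropy, d_long=d_cal)
            subs[c["seed"]].manifest["seed"] = c["seed"]
        cond = Condition(c["genotype"], "AF", c["drug"], c["dose"])
        try:
            row = run_single_case(subs[c["seed"]], cond, design,
                                  drug_table, run_af=run_af)
            row["status"] = "ok"
        except Exception as e:       # individual case failure is not fatal
            row = {"genotype": c["genotype"], "drug": c["drug"],
                   "dose": c["dose"], "seed": c["seed"],
                   "drug_class": conditions.DRUG_CLASS.get(c["drug"]),
                   "status": f"failed: {e}"}
        if progress:
            print(f"[{i + 1}/{len(all_cases)}] {tag}: {row.get('status')}",
                  flush=True)
        if ckpt:
            ckpt.write_text(json.dumps(row, default=_json_default))
        rows.append(row)

    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"].copy() if "status" in df else df
    summaries = summarize(ok) if len(ok) else {}
    term = termination_table(ok) if (ok.get("drug") != "none").any() else pd.DataFrame()
    manifest = {"design": asdict(design), "master_seed": master_seed,
                "n_cases": len(df),
                "scaled_down": design.scaled_down,
                "drug_table": drug_table.blocks,
                "note": "no multiple-testing correction applied"}
    report = TrialReport(cases=df, summaries=summaries, termination=term,
                         manifest=manifest)
    if out_dir:
        report.save(out_dir)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, ConductanceScales):
        return o.as_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
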