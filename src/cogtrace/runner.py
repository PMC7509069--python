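"""Study orchestration: replicated simulation conditions and empirical runs.

``make_condition`` assembles a full simulation condition (Q matrix, item
parameters, study design) from the factor levels of the simulation study —
attributes (3/6), items (20/40), sample size, discrimination regime.  The
40-item forms stack the published 20-item Q twice and draw fresh slip/guess
from the regime's uniform range, preserving attribute coverage.

``run_condition`` repeats simulate -> fit -> score over replications and
aggregates ACCR/PCCR and transition agreement; ``run_empirical`` applies the
pipeline to observed response CSVs for two or more waves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._validate import ValidationError
from .design import ItemParams, QMatrix, StudyDesign
from .fixtures import builtin_fixture, default_initial_mastery
from .metrics import aggregate
from .model import LongitudinalCDA, default_ssom_config
from .simulate import simulate_longitudinal
from .ssom import SSOMConfig

__all__ = ["Condition", "make_condition", "run_condition", "ConditionResult",
           "run_empirical", "run_grid"]


@dataclass(frozen=True)
class Condition:
    """A simulation condition: design plus the item bank realizing it."""

    design: StudyDesign
    q: QMatrix
    params: ItemParams | None   # None => redraw from the regime per replication
    label: str = ""


def _forty_item_q(q20: QMatrix) -> QMatrix:
    return QMatrix(entries=np.vstack([q20.entries, q20.entries]))


def make_condition(k: int, j: int, n: int, regime: str,
                   n_waves: int = 3, replications: int = 30,
                   fixed_params: bool | None = None) -> Condition:
    """Assemble a study condition from its factor levels.

    ``fixed_params=True`` uses the published 20-item slip/guess draw (only
    available for 20-item forms); ``False`` redraws from the regime's range
    every replication.  The default fixes parameters for 20 items and
    redraws for 40.
    """
    if k not in (3, 6):
        raise ValidationError("attribute count must be 3 or 6")
    if j not in (20, 40):
        raise ValidationError("item count must be 20 or 40")
    q20 = builtin_fixture(f"q{k}_20")
    q = q20 if j == 20 else _forty_item_q(q20)
    if fixed_params is None:
        fixed_params = j == 20
    params = None
    if fixed_params:
        if j != 20:
            raise ValidationError("fixed published parameters exist for 20 items only")
        suffix = "" if k == 3 else "_k6"
        params = builtin_fixture(f"params_{regime}_20{suffix}")
    transitions = builtin_fixture(f"transitions_k{k}")[: n_waves - 1]
    design = StudyDesign(n_attributes=k, n_items=j, n_examinees=n, regime=regime,
                         initial_mastery=default_initial_mastery(k),
                         transitions=transitions, n_waves=n_waves,
                         replications=replications)
    return Condition(design=design, q=q, params=params,
                     label=f"k{k}_j{j}_n{n}_{regime}")


@dataclass
class ConditionResult:
    """Aggregated accuracy and transition agreement for one condition."""

    condition: Condition
    accuracy: pd.DataFrame       # aggregate() layout per time point
    transition: pd.DataFrame     # per interval: pairwise / matrix agreement
    replication_frame: pd.DataFrame  # raw per-replication metrics
    seed: object = None


def run_condition(condition: Condition, ssom_config: SSOMConfig | None = None,
                  replications: int | None = None, seed=None,
                  training: str = "population") -> ConditionResult:
    """Run one condition end to end over seeded replications and aggregate."""
    design = condition.design
    reps = replications if replications is not None else design.replications
    if reps < 1:
        raise ValidationError("replications must be >= 1")
    ssom_config = ssom_config or default_ssom_config(design.n_attributes)
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = root.spawn(reps)
    reports, rows = [], []
    agg_pairs = {}
    failures = []
    for r, ss in enumerate(streams):
        try:
            ss_params, ss_sim, ss_fit = ss.spawn(3)
            params = condition.params
            if params is None:
                params = ItemParams.draw(design.n_items, design.regime,
                                         np.random.default_rng(ss_params))
            sample = simulate_longitudinal(design, condition.q, params, seed=ss_sim)
            model = LongitudinalCDA(sample.responses, condition.q,
                                    ssom_config=ssom_config, training=training,
                                    initial_mastery=design.initial_mastery,
                                    correlation=design.initial_correlation)
            res = model.fit(seed=ss_fit)
            scored = res.score(sample.profiles)
        except Exception as exc:  # pragma: no cover - defensive bookkeeping
            failures.append((r, repr(exc)))
            continue
        reports.extend(scored["reports"])
        for t, agr in enumerate(scored["agreements"]):
            agg_pairs.setdefault(t, []).append(agr)
        for rep in scored["reports"]:
            row = {"replication": r, "time_point": rep.time_point,
                   "pccr": rep.pccr}
            row.update({f"A{a + 1}": rep.accr[a] for a in range(rep.n_attributes)})
            rows.append(row)
        for t, agr in enumerate(scored["agreements"]):
            rows.append({"replication": r, "time_point": f"T{t + 1}-T{t + 2}",
                         "pairwise": agr.pairwise, "matrix": agr.matrix})
    if failures:
        raise RuntimeError(f"{len(failures)} replications failed: {failures}")
    trans_rows = []
    for t, agrs in sorted(agg_pairs.items()):
        pw = np.array([a.pairwise for a in agrs])
        mx = np.array([a.matrix for a in agrs])
        trans_rows.append({
            "interval": f"T{t + 1}-T{t + 2}", "replications": len(agrs),
            "pairwise": pw.mean(),
            "pairwise_se": pw.std(ddof=1) / np.sqrt(len(pw)) if len(pw) > 1 else np.nan,
            "matrix": np.nanmean(mx),
            "matrix_se": (np.nanstd(mx, ddof=1) / np.sqrt(len(mx))
                          if len(mx) > 1 else np.nan),
        })
    return ConditionResult(condition=condition, accuracy=aggregate(reports),
                           transition=pd.DataFrame(trans_rows),
                           replication_frame=pd.DataFrame(rows), seed=seed)


def run_grid(ks=(3, 6), js=(20, 40), ns=(200, 500, 1000),
             regimes=("high", "mixed"), replications: int = 10, seed=None,
             n_waves: int = 3, training: str = "population") -> pd.DataFrame:
    """Run the full factorial design and return one tidy summary frame."""
    root = np.random.SeedSequence(seed)
    rows = []
    for k in ks:
        for j in js:
            for n in ns:
                for regime in regimes:
                    cond = make_condition(k, j, n, regime, n_waves=n_waves,
                                          replications=replications)
                    res = run_condition(cond, replications=replications,
                                        seed=root.spawn(1)[0], training=training)
                    acc = res.accuracy.assign(k=k, j=j, n=n, regime=regime,
                                              measure="accuracy")
                    tr = res.transition.assign(k=k, j=j, n=n, regime=regime,
                                               measure="transition")
                    rows.extend([acc, tr])
    return pd.concat(rows, ignore_index=True)


def run_empirical(wave_csvs, q: QMatrix | str, ssom_config: SSOMConfig | None = None,
                  training: str = "uniform", initial_mastery=None,
                  seed=None, out_dir=None):
    """Two-step pipeline on observed response CSVs for two or more waves.

    Trains the SSOM on the ideal responses implied by ``q`` (uniform pattern
    weights by default, since the empirical mastery distribution is unknown),
    classifies every wave, and returns the fitted results; ``out_dir`` writes
    the mastery/transition/trajectory tables.
    """
    from .design import load_q_matrix
    if isinstance(q, (str, bytes)) or hasattr(q, "__fspath__"):
        q = load_q_matrix(q)
    if len(wave_csvs) < 2:
        raise ValidationError("need at least two waves for a longitudinal run")
    if ssom_config is None and q.n_attributes == 3:
        # 8 classes: a 9x9 grid keeps ~8-10 neurons per pattern
        ssom_config = SSOMConfig(grid_shape=(9, 9), iterations=3)
    model = _model_from_paths(wave_csvs, q, ssom_config, training,
                              initial_mastery)
    results = model.fit(seed=seed)
    if out_dir is not None:
        results.save(out_dir)
    return results


def _model_from_paths(wave_csvs, q, ssom_config, training, initial_mastery):
    from .design import load_responses
    waves = [load_responses(p, time_point=f"T{t + 1}")
             for t, p in enumerate(wave_csvs)]
    return LongitudinalCDA(waves, q, ssom_config=ssom_config, training=training,
                           initial_mastery=initial_mastery)
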