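"""Synthetic hospital-episode data generator.

Emulates, at the statistical level, the patient-level extract the analyses
consume: practice registers with an age-sex structure and a deprivation
mixture, elective back-pain episodes (attendances and procedures) with
practice- and deprivation-structured rate variation, and an intervention
portfolio table.

Model
-----
Episode counts are Poisson per (practice, age band, sex, IMD decile, fiscal
year) stratum with mean::

    base_rate * age_sex_multiplier * exp(practice_effect)
              * decile_multiplier * person_years

where ``practice_effect ~ Normal(0, practice_sigma^2)`` and the decile
multiplier is log-linear in decile, pinned so decile 1 (most deprived) over
decile 10 equals ``decile_rate_ratio``.  Procedures are a fraction
``procedure_fraction`` of activity in expectation; their age distribution is
a normal over bands whose mean falls by ``age_shift_years`` per deprivation
step, so the decile-1 vs decile-10 mean-age gap is ``9 * age_shift_years``.

Each practice draws a decile *mixture* around a random centre, making the
register-weighted mean decile (the recorded practice deprivation score) a
deliberately noisy proxy for the deprivation of individual patients.

All randomness flows from ``config.seed`` through fixed named substreams,
so adding a generator never perturbs the others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import bands as _bands
from .config import SimulationConfig
from .errors import InputError
from .star import Intervention

__all__ = [
    "generate_registers",
    "generate_episodes",
    "generate_portfolio",
    "synthetic_baseline_portfolio",
    "REGISTER_COLUMNS",
    "EPISODE_COLUMNS",
]

REGISTER_COLUMNS = [
    "practice_id", "age_band", "sex", "imd_decile", "count", "deprivation_score",
]
EPISODE_COLUMNS = [
    "patient_id", "age", "sex", "practice_id", "imd_decile",
    "fiscal_year", "event_class", "intervention_id",
]

_SUBSTREAMS = {"registers": 0, "episodes": 1, "portfolio": 2}

DECILES = np.arange(1, 11)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[stream],))
    )


def _decile_mixture(centre: float, sd: float) -> np.ndarray:
    """Probability over deciles 1..10: discretised normal around `centre`."""
    edges = np.arange(0.5, 11.0)
    cdf = norm.cdf(edges, loc=centre, scale=sd)
    p = np.diff(cdf)
    return p / p.sum()


def _esp_band_probs(age_bands: tuple[str, ...]) -> np.ndarray:
    # register age structure proportional to the adult ESP weights keeps the
    # synthetic population's shape close to the standard one
    from .standardise import ESP_2013

    w = np.array([ESP_2013.weights[b] for b in age_bands], dtype=float)
    return w / w.sum()


def generate_registers(config: SimulationConfig) -> pd.DataFrame:
    """Generate one register per practice.

    Returns a long DataFrame with columns ``practice_id, age_band, sex,
    imd_decile, count, deprivation_score``; the deprivation score is the
    register-weighted mean decile (lower = more deprived).  Deterministic
    given ``config.seed``.
    """
    rng = _rng(config.seed, "registers")
    bands = config.age_bands
    p_band = _esp_band_probs(bands)
    lo, hi = config.register_size_range

    nb, ns, nd = len(bands), 2, 10
    frames = []
    for i in range(config.n_practices):
        pid = f"prac{i + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        centre = rng.uniform(1.0, 10.0)
        p_dec = _decile_mixture(centre, config.decile_mix_sd)
        # joint allocation over band x sex x decile
        probs = (
            p_band[:, None, None] * np.array([0.5, 0.5])[None, :, None]
            * p_dec[None, None, :]
        ).ravel()
        counts = rng.multinomial(size, probs).reshape(nb, ns, nd)
        dec_totals = counts.sum(axis=(0, 1)).astype(float)
        score = float((dec_totals * DECILES).sum() / dec_totals.sum())
        b_idx, s_idx, d_idx = np.indices((nb, ns, nd))
        frames.append(pd.DataFrame({
            "practice_id": pid,
            "age_band": np.asarray(bands, dtype=object)[b_idx.ravel()],
            "sex": np.array(["F", "M"], dtype=object)[s_idx.ravel()],
            "imd_decile": DECILES[d_idx.ravel()],
            "count": counts.ravel(),
            "deprivation_score": score,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out[out["count"] > 0].reset_index(drop=True)


def _decile_multipliers(ratio: float) -> np.ndarray:
    """Log-linear decile rate multipliers; decile 10 = 1, decile 1 = ratio."""
    return ratio ** ((10.0 - DECILES) / 9.0)


def _procedure_band_weights(config: SimulationConfig) -> np.ndarray:
    """(n_bands x 10) matrix: probability a procedure in decile d falls in
    band b, from a normal age distribution whose mean drops by
    ``age_shift_years`` per step of deprivation."""
    bands = config.age_bands
    mus = config.procedure_age_mean - config.age_shift_years * (10.0 - DECILES)
    g = np.empty((len(bands), 10))
    for j, mu in enumerate(mus):
        for i, b in enumerate(bands):
            a_lo, a_hi = _bands.sampling_bounds(b)
            g[i, j] = norm.cdf(a_hi + 1, mu, config.procedure_age_sd) - norm.cdf(
                a_lo, mu, config.procedure_age_sd
            )
        g[:, j] /= g[:, j].sum()
    return g


def generate_episodes(
    config: SimulationConfig, registers: pd.DataFrame
) -> pd.DataFrame:
    """Generate elective episodes for the registered population.

    One row per hospital contact with columns ``patient_id, age, sex,
    practice_id, imd_decile, fiscal_year, event_class, intervention_id``.
    Patients are single-episode unless ``repeat_episode_rate > 0``.
    """
    if registers is None or len(registers) == 0:
        raise InputError("registers is empty; run generate_registers first")
    rng = _rng(config.seed, "episodes")
    bands = list(config.age_bands)
    mult = config.multipliers()
    pf = config.procedure_fraction

    practices = list(dict.fromkeys(registers["practice_id"]))
    pe = dict(zip(
        practices,
        np.exp(rng.normal(0.0, config.practice_sigma, len(practices))),
    ))

    reg = registers.copy()
    reg["mult"] = [mult[b][s] for b, s in zip(reg["age_band"], reg["sex"])]
    reg["pe"] = reg["practice_id"].map(pe)
    dm = _decile_multipliers(config.decile_rate_ratio)
    reg["dm"] = dm[reg["imd_decile"].to_numpy() - 1]
    # procedure age allocation across bands, per decile
    g = _procedure_band_weights(config)
    band_idx = {b: i for i, b in enumerate(bands)}
    reg["g"] = g[
        [band_idx[b] for b in reg["age_band"]], reg["imd_decile"].to_numpy() - 1
    ]
    # total age-weighted register per (practice, sex, decile): the procedure
    # intensity scale, so the marginal procedure share equals pf
    reg["mc"] = reg["mult"] * reg["count"]
    reg["T"] = reg.groupby(["practice_id", "sex", "imd_decile"])["mc"].transform("sum")

    strata = pd.concat(
        [reg.assign(fiscal_year=y) for y in config.years], ignore_index=True
    )
    lam_common = config.base_rate * strata["pe"] * strata["dm"]
    lam_att = lam_common * (1.0 - pf) * strata["mult"] * strata["count"]
    lam_proc = lam_common * pf * strata["g"] * strata["T"]
    strata["n_att"] = rng.poisson(lam_att.to_numpy())
    strata["n_proc"] = rng.poisson(lam_proc.to_numpy())

    parts = []
    for cls, col in (("attendance", "n_att"), ("procedure", "n_proc")):
        ev = strata[strata[col] > 0]
        n = ev[col].to_numpy()
        rep = ev.loc[ev.index.repeat(n)]
        lows = np.array([_bands.sampling_bounds(b)[0] for b in rep["age_band"]])
        highs = np.array([_bands.sampling_bounds(b)[1] for b in rep["age_band"]])
        ages = rng.integers(lows, highs + 1)
        parts.append(pd.DataFrame({
            "age": ages,
            "sex": rep["sex"].to_numpy(),
            "practice_id": rep["practice_id"].to_numpy(),
            "imd_decile": rep["imd_decile"].to_numpy(),
            "fiscal_year": rep["fiscal_year"].to_numpy(),
            "event_class": cls,
            "intervention_id": "spinal_procedure" if cls == "procedure" else "",
        }))
    episodes = pd.concat(parts, ignore_index=True)
    episodes.insert(
        0, "patient_id",
        [f"{p}-pt{k:06d}" for k, p in enumerate(episodes["practice_id"])],
    )

    if config.repeat_episode_rate > 0 and len(episodes):
        extra = rng.poisson(config.repeat_episode_rate, len(episodes))
        rep = episodes.loc[episodes.index.repeat(extra)].copy()
        if len(rep):
            rep["fiscal_year"] = rng.choice(config.years, len(rep))
            episodes = pd.concat([episodes, rep], ignore_index=True)

    return episodes[EPISODE_COLUMNS].reset_index(drop=True)


def generate_portfolio(config: SimulationConfig) -> list[Intervention]:
    """Materialise ``config.portfolio_spec`` as Intervention objects."""
    if not config.portfolio_spec:
        raise InputError("portfolio_spec is empty")
    out = []
    for i, row in enumerate(config.portfolio_spec):
        if row.n_treated < 0 or row.fixed_cost < 0 or row.variable_cost_per_person < 0:
            raise InputError(f"portfolio_spec row {i}: negative cost or n_treated")
        out.append(Intervention(
            id=row.name.lower().replace(" ", "_"),
            name=row.name,
            n_treated=row.n_treated,
            fixed_cost=row.fixed_cost,
            variable_cost_per_person=row.variable_cost_per_person,
            qaly_per_person=row.qaly_per_person,
            evidence_category=row.evidence_category,
        ))
    return out


def synthetic_baseline_portfolio() -> list[Intervention]:
    """A synthetic 29-intervention baseline back-pain portfolio.

    The real service-level finance table is not public; this stand-in is
    constructed to reproduce its published margins exactly: 29 interventions
    (16 with evidence of benefit, 9 with no evidence, 3 with evidence of no
    benefit, 1 with possible harm), 17,225 people treated, £4.5 million
    total spend, and a population gain of 4,571 QALYs.  Zero-QALY
    disinvestment candidates (imaging outside guidelines and injections
    with no evidence of benefit) carry £270,000 of variable spend between
    them.  Costs are modelled as fully variable.
    """

    def iv(id_, name, n, var_cost, qpp, cat):
        return Intervention(
            id=id_, name=name, n_treated=n, fixed_cost=0.0,
            variable_cost_per_person=var_cost, qaly_per_person=qpp,
            evidence_category=cat,
        )

    rows: list[Intervention] = [
        # --- possible harm (1): MRI outside guidelines -------------------
        iv("mri_outside_guidelines", "MRI scan outside guidelines",
           800, 150.0, 0.0, "possible_harm"),
        # --- no benefit (3) ----------------------------------------------
        iv("xray_spine", "X-ray spine", 1_200, 50.0, 0.0, "no_benefit"),
        iv("facet_injection", "Injection around spinal facet",
           200, 200.0, 0.0, "no_benefit"),
        iv("joint_injection", "Injection of therapeutic substance into joint",
           150, 200.0, 0.0, "no_benefit"),
        # --- no evidence (9) ---------------------------------------------
        iv("trigger_point_injection", "Trigger point injection",
           100, 200.0, 0.0, "no_evidence"),
    ]
    for k in range(8):
        rows.append(iv(
            f"no_evidence_{k + 1:02d}", f"Procedure without evidence {k + 1}",
            100, 150.0, 0.0, "no_evidence",
        ))
    # --- evidence of benefit (16); residual row balances the margins -----
    benefit = [
        ("physiotherapy", "Physiotherapy", 5_000, 160.0, 0.20),
        ("pain_management_programme", "Pain management programme",
         400, 1_000.0, 1.20),
        ("spinal_decompression", "Spinal decompression surgery",
         250, 3_200.0, 1.50),
        ("nerve_root_injection", "Nerve root injection", 500, 400.0, 0.30),
        ("epidural_injection", "Epidural injection", 400, 400.0, 0.25),
        ("combined_physical_psych", "Combined physical and psychological programme",
         300, 1_200.0, 1.10),
        ("exercise_programme", "Group exercise programme", 1_200, 90.0, 0.25),
        ("acupuncture", "Acupuncture course", 600, 120.0, 0.15),
        ("cbt_back_pain", "CBT for back pain", 400, 300.0, 0.40),
        ("radiofrequency_denervation", "Radiofrequency denervation",
         200, 900.0, 0.80),
        ("orthopaedic_triage", "Orthopaedic triage clinic", 900, 100.0, 0.05),
        ("pain_clinic", "Outpatient pain clinic", 700, 220.0, 0.30),
        ("manual_therapy", "Manual therapy", 600, 110.0, 0.10),
        ("back_school", "Back school education course", 500, 70.0, 0.12),
        ("tens_service", "TENS service", 300, 50.0, 0.05),
    ]
    for id_, name, n, c, q in benefit:
        rows.append(iv(id_, name, n, c, q, "benefit"))

    target_people, target_cost, target_qaly = 17_225, 4_500_000.0, 4_571.0
    n_res = target_people - sum(r.n_treated for r in rows)
    cost_res = target_cost - sum(r.total_cost for r in rows)
    qaly_res = target_qaly - sum(r.total_qaly for r in rows)
    assert n_res > 0 and cost_res > 0 and qaly_res > 0
    rows.append(iv(
        "fcp_assessment", "First-contact practitioner assessment",
        n_res, cost_res / n_res, qaly_res / n_res, "benefit",
    ))
    assert len(rows) == 29
    return rows
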