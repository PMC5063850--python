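"""Synthetic compound datasets with the statistical structure the pipeline
assumes.

The generator emulates the *categorical* structure of a subchronic-plus-
bioassay compound table: compounds grouped in pharmacological classes,
per-class carcinogenicity, a hyperplasia signal generated conditionally on
carcinogenicity (a sensitivity and a false-positive rate), optional organ
concordance between the hyperplastic lesion and a tumor, and tumor types
drawn from human-relevant versus non-relevant pools.  It makes every stage
testable without the reference fixture and supports parameter-recovery
experiments: stage-1 sensitivity/specificity estimated by the pipeline on a
generated dataset converge to the configured values as n grows.

Default parameter values are the rates observed in the 289-compound
reference dataset (carcinogen prevalence 0.44, hyperplasia sensitivity
0.244, false-positive rate 0.117, organ concordance 0.42, non-relevant
tumor fraction 0.8); organ/morphology pools default to the fixture's
observed vocabulary with empirical frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dataset import CompoundRecord, Dataset, Finding, load_fixture
from .vocab import load_default_relevance_rules, is_human_relevant

__all__ = ["SimulationConfig", "generate", "load_simulation_config", "default_pools"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic compound generator (all fractions in [0, 1])."""

    n_classes: int = 52
    class_size_min: int = 1
    class_size_max: int = 13
    per_class_carcinogen_probability: float | tuple[float, ...] = 0.44
    hyperplasia_sensitivity: float = 0.244
    hyperplasia_false_positive_rate: float = 0.117
    same_organ_probability: float = 0.42
    nonrelevant_tumor_fraction: float = 0.80
    hypertrophy_rate: float = 0.12
    weight_finding_rate: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 1 <= self.class_size_min <= self.class_size_max:
            raise ValueError("class sizes must satisfy 1 <= min <= max")
        probs = self.per_class_carcinogen_probability
        probs = probs if isinstance(probs, tuple) else (probs,)
        for name, val in [
            ("per_class_carcinogen_probability", min(probs)),
            ("per_class_carcinogen_probability", max(probs)),
            ("hyperplasia_sensitivity", self.hyperplasia_sensitivity),
            ("hyperplasia_false_positive_rate", self.hyperplasia_false_positive_rate),
            ("same_organ_probability", self.same_organ_probability),
            ("nonrelevant_tumor_fraction", self.nonrelevant_tumor_fraction),
            ("hypertrophy_rate", self.hypertrophy_rate),
            ("weight_finding_rate", self.weight_finding_rate),
        ]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name}={val} outside [0, 1]")

    def class_probability(self, k: int, rng: np.random.Generator) -> float:
        probs = self.per_class_carcinogen_probability
        if isinstance(probs, tuple):
            return probs[k % len(probs)]
        return probs


@lru_cache(maxsize=1)
def default_pools() -> dict[str, tuple]:
    """Empirical token pools from the packaged reference dataset.

    Returns organ and (organ, morphology) pools with their observed
    frequencies; tumor pairs are split into human-relevant and non-relevant
    pools by the packaged relevance rules.
    """
    ds = load_fixture()
    rules = load_default_relevance_rules()
    organ_counts: dict[str, int] = {}
    rel: dict[tuple[str, str], int] = {}
    nonrel: dict[tuple[str, str], int] = {}
    for rec in ds:
        for f in (
            rec.weight_findings + rec.hypertrophy_findings + rec.hyperplasia_findings
        ):
            organ_counts[f.organ] = organ_counts.get(f.organ, 0) + 1
        for f in rec.tumor_findings:
            pair = (f.organ, f.morphology)
            bucket = rel if is_human_relevant(f, rules) else nonrel
            bucket[pair] = bucket.get(pair, 0) + 1
    return {
        "organs": tuple(sorted(organ_counts.items())),
        "relevant_tumors": tuple(sorted(rel.items())),
        "nonrelevant_tumors": tuple(sorted(nonrel.items())),
    }


class _Pool:
    """Weighted sampler over a frequency pool (inverse-CDF draw)."""

    def __init__(self, pool: Sequence[tuple]):
        self.items = [item for item, _ in pool]
        cum = np.cumsum([w for _, w in pool], dtype=float)
        self.cum = cum / cum[-1]

    def draw(self, rng: np.random.Generator):
        return self.items[int(np.searchsorted(self.cum, rng.random(), side="right"))]


def generate(cfg: SimulationConfig) -> Dataset:
    """Generate a synthetic compound dataset.

    One seeded generator (``cfg.seed``) is threaded through all draws, so a
    fixed config is fully reproducible.  Published-category fields are left
    empty: synthetic data has no ground truth other than what the generator
    drew, which the pipeline is expected to recover.
    """
    rng = np.random.default_rng(cfg.seed)
    pools = default_pools()
    organ_pool = _Pool(pools["organs"])
    relevant_pool = _Pool(pools["relevant_tumors"])
    nonrelevant_pool = _Pool(pools["nonrelevant_tumors"])
    records: list[CompoundRecord] = []
    cid = 0
    for k in range(cfg.n_classes):
        size = int(rng.integers(cfg.class_size_min, cfg.class_size_max + 1))
        p_carc = cfg.class_probability(k, rng)
        for _ in range(size):
            cid += 1
            carcinogen = rng.random() < p_carc
            tumors: tuple[Finding, ...] = ()
            if carcinogen:
                n_tum = int(rng.integers(1, 4))
                pairs = []
                for _ in range(n_tum):
                    pool = (
                        nonrelevant_pool
                        if rng.random() < cfg.nonrelevant_tumor_fraction
                        else relevant_pool
                    )
                    pairs.append(pool.draw(rng))
                tumors = tuple(Finding(o, m) for o, m in pairs)
            p_hp = (
                cfg.hyperplasia_sensitivity
                if carcinogen
                else cfg.hyperplasia_false_positive_rate
            )
            hyperplasia: tuple[Finding, ...] = ()
            if rng.random() < p_hp:
                if tumors and rng.random() < cfg.same_organ_probability:
                    organ = tumors[0].organ
                else:
                    organ = organ_pool.draw(rng)
                hyperplasia = (Finding(organ),)
            hypertrophy: tuple[Finding, ...] = ()
            if rng.random() < cfg.hypertrophy_rate:
                hypertrophy = (Finding(organ_pool.draw(rng)),)
            weight: tuple[Finding, ...] = ()
            if rng.random() < cfg.weight_finding_rate:
                weight = (Finding(organ_pool.draw(rng)),)
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    mode_of_action=f"SIM, class {k + 1}",
                    therapeutic_area="ZZ",
                    pharm_class_id=f"sim:{k + 1}",
                    weight_findings=weight,
                    hypertrophy_findings=hypertrophy,
                    hyperplasia_findings=hyperplasia,
                    tumor_findings=tumors,
                )
            )
    return Dataset(records=records, provenance=f"synthetic (seed={cfg.seed})")


def load_simulation_config(path: Path | str) -> SimulationConfig:
    """Read a YAML key/value file into a :class:`SimulationConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "per_class_carcinogen_probability" in raw and isinstance(
        raw["per_class_carcinogen_probability"], list
    ):
        raw["per_class_carcinogen_probability"] = tuple(
            raw["per_class_carcinogen_probability"]
        )
    return SimulationConfig(**raw)
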