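"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected results by direct loops over the written
filtering rules, kept deliberately separate from the package's
implementations so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from evohotspot import simdata
from evohotspot.variants import SampleCall, VariantRecord, VariantTable


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(
        seed=7, n_mutants_per_background=30, n_precultures=6
    )


@pytest.fixture(scope="session")
def genome(small_config):
    return simdata.generate_genome(small_config)


@pytest.fixture(scope="session")
def truth(small_config, genome):
    return simdata.simulate_cohort(genome, small_config)


# ---------------------------------------------------------------------------
# random variant tables (for oracle-equivalence tests)


def make_record(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    qual=200.0,
    calls=None,
    **annotations,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        annotations=annotations,
        calls=calls or {},
    )


def clean_annotations() -> dict:
    return {
        "QD": 20.0,
        "MQ": 58.0,
        "FS": 3.0,
        "SOR": 1.0,
        "MQRankSum": 0.0,
        "ReadPosRankSum": 0.0,
    }


def random_variant_table(rng: np.random.Generator, n_samples=6, max_records=50):
    """A random table spanning both sides of every filter threshold."""
    samples = [f"s{i}" for i in range(n_samples)] + ["parent"]
    n_records = int(rng.integers(1, max_records + 1))
    records = []
    for i in range(n_records):
        is_indel = rng.random() < 0.3
        ref = "A"
        alt = "AT" if is_indel else "T"
        annotations = {}
        for key, lo, hi in [
            ("QD", 0.0, 10.0),
            ("MQ", 20.0, 60.0),
            ("FS", 0.0, 300.0),
            ("SOR", 0.0, 8.0),
            ("MQRankSum", -20.0, 5.0),
            ("ReadPosRankSum", -25.0, 5.0),
        ]:
            if rng.random() < 0.9:  # ~10% missing to exercise fail-closed
                annotations[key] = float(rng.uniform(lo, hi))
        qual = float(rng.uniform(0, 100)) if rng.random() < 0.95 else None
        calls = {}
        for s in samples:
            dp = int(rng.integers(0, 40))
            ad_alt = int(rng.integers(0, dp + 1))
            ad = (dp - ad_alt, ad_alt)
            gt = int(rng.random() < 0.3)
            if rng.random() < 0.05:
                ad = (0, 0)
            calls[s] = SampleCall(s, gt, dp, ad)
        records.append(
            VariantRecord(
                chrom="chr1",
                pos=i + 1,
                ref=ref,
                alt=alt,
                qual=qual,
                annotations=annotations,
                calls=calls,
            )
        )
    return VariantTable(records=records, samples=samples)


# ---------------------------------------------------------------------------
# brute-force cascade oracle (independent of evohotspot.variants internals)

_SNP_RULES = [
    ("QUAL", "lt", 30.0),
    ("QD", "lt", 2.0),
    ("MQ", "lt", 40.0),
    ("FS", "gt", 60.0),
    ("SOR", "gt", 4.0),
    ("MQRankSum", "lt", -12.5),
    ("ReadPosRankSum", "lt", -8.0),
]
_INDEL_RULES = [
    ("QD", "lt", 2.0),
    ("QUAL", "lt", 30.0),
    ("FS", "gt", 200.0),
    ("ReadPosRankSum", "lt", -20.0),
]


def cascade_oracle_surviving(table: VariantTable, parental_ids) -> set:
    """Surviving (chrom, pos, ref, alt) after a direct loop over the rules."""
    parental = set(parental_ids)
    surviving = set()
    for rec in table.records:
        is_indel = len(rec.ref) != len(rec.alt)
        rules = _INDEL_RULES if is_indel else _SNP_RULES
        hard_fail = False
        for key, op, thr in rules:
            val = rec.qual if key == "QUAL" else rec.annotations.get(key)
            if val is None:
                hard_fail = True  # missing annotation fails closed
            elif op == "lt" and val < thr:
                hard_fail = True
            elif op == "gt" and val > thr:
                hard_fail = True
        if hard_fail:
            continue
        # per-sample masking
        masked = {}
        for s, call in rec.calls.items():
            dp = call.dp or 0
            ads = sorted(call.ad, reverse=True) or [0]
            ad1 = ads[0]
            ad2 = ads[1] if len(ads) > 1 else 0
            masked[s] = (
                dp < 4
                or (ad1 == 0 and dp > 0)
                or ad2 > 4
                or (ad1 > 0 and ad2 / ad1 > 0.2)
            )
        # cohort-level rules
        dps = [c.dp for c in rec.calls.values() if c.dp is not None]
        mean_dp = sum(dps) / len(dps) if dps else 0.0
        total_dp = rec.annotations.get("DP", float(sum(dps)))
        ac = sum(
            1
            for s, c in rec.calls.items()
            if s not in parental and not masked[s] and c.gt == 1
        )
        n_called = sum(
            1
            for s, c in rec.calls.items()
            if s not in parental and not masked[s] and c.gt is not None
        )
        af = ac / n_called if n_called else 0.0
        mq = rec.annotations.get("MQ")
        shared_parent = any(
            c.gt == 1 and not masked[s]
            for s, c in rec.calls.items()
            if s in parental
        )
        if (
            mean_dp < 10
            or total_dp > 20000
            or rec.qual is None
            or rec.qual < 20
            or mq is None
            or mq < 40
            or af > 0.99
            or ac == 0
            or shared_parent
        ):
            continue
        surviving.add((rec.chrom, rec.pos, rec.ref, rec.alt))
    return surviving
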