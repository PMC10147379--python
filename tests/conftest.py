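import numpy as np
import pytest

from tsmr.harmonize import HarmonizedRecord, HarmonizedSet
from tsmr.sumstats import SummaryRecord, SummaryStatsTable


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02, **kw):
    return SummaryRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se, **kw
    )


def make_table(records, name="trait", trait_type="continuous"):
    return SummaryStatsTable(records=list(records), trait_name=name, trait_type=trait_type)


def hset_from_arrays(bx, bxse, by, byse, outcome_type="continuous", eaf=None):
    """Build a HarmonizedSet directly from effect arrays."""
    records = []
    for i, (x, xs, y, ys) in enumerate(zip(bx, bxse, by, byse)):
        records.append(
            HarmonizedRecord(
                snp_id=f"rs{i + 1}",
                beta_exp=float(x),
                se_exp=float(xs),
                beta_out=float(y),
                se_out=float(ys),
                eaf_exp=None if eaf is None else float(eaf[i]),
                eaf_out=None if eaf is None else float(eaf[i]),
                status="aligned",
            )
        )
    return HarmonizedSet(
        records=records,
        audit={"aligned": len(records)},
        exposure_name="exp",
        outcome_name="out",
        outcome_type=outcome_type,
    )


def flipped_set(hset, indices):
    """Re-orient the given records (negate both betas), as an allele flip would."""
    recs = []
    for i, r in enumerate(hset.records):
        if i in indices:
            r = HarmonizedRecord(
                snp_id=r.snp_id,
                beta_exp=-r.beta_exp,
                se_exp=r.se_exp,
                beta_out=-r.beta_out,
                se_out=r.se_out,
                eaf_exp=r.eaf_exp,
                eaf_out=r.eaf_out,
                status=r.status,
            )
        recs.append(r)
    return HarmonizedSet(
        records=recs,
        audit=dict(hset.audit),
        exposure_name=hset.exposure_name,
        outcome_name=hset.outcome_name,
        outcome_type=hset.outcome_type,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hset(rng):
    """A well-conditioned 6-SNP harmonized set with heterogeneous weights."""
    bx = np.array([0.08, 0.05, 0.12, 0.09, 0.06, 0.11])
    bxse = np.array([0.004, 0.005, 0.006, 0.004, 0.005, 0.006])
    by = np.array([0.021, 0.008, 0.035, 0.030, 0.011, 0.028])
    byse = np.array([0.010, 0.012, 0.015, 0.011, 0.013, 0.014])
    return hset_from_arrays(bx, bxse, by, byse, outcome_type="binary")
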