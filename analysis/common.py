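"""Shared study configuration for the analysis scripts.

One synthetic FAERS-like corpus defines the study: 563 target-drug reports
(the pralatrexate-scale case series) against a 20,000-report background,
with planted mucosal/hematologic/hepatic/dermatologic associations,
Weibull(45.74 d, 0.63) onset times, ~44% of reports without a computable
onset, 10% duplicated case versions and 2% deleted cases.  Every script
regenerates deterministically from STUDY_SEED, so each one can be run on
its own.
"""

from pathlib import Path

from pvsignal.config import PipelineConfig
from pvsignal.pipeline import clean_cases, load_input_tables
from pvsignal.synthetic import PlantedSignalSpec

STUDY_SEED = 20090924  # pralatrexate's US approval date
RESULTS = Path(__file__).resolve().parent.parent / "results" / "tables"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_config() -> PipelineConfig:
    config = PipelineConfig(
        synthetic=PlantedSignalSpec(seed=STUDY_SEED),
        target_drug="pralatrexate",
    )
    config.signal.seed = STUDY_SEED
    return config


def load_populations(config: PipelineConfig | None = None):
    """(target, background, cleaning counts) for the study corpus."""
    config = config or study_config()
    tables, deleted = load_input_tables(config)
    return clean_cases(tables, deleted, config)
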