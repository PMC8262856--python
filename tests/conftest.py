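import pytest

from hipsurvey.genome_io import parse_genome
from hipsurvey.pipeline import SurveySettings, run_survey
from hipsurvey.synth import GeneratorConfig, generate_genome


@pytest.fixture(scope="session")
def zero_div_dataset():
    """One module per layout at zero divergence plus decoys, with truth."""
    cfg = GeneratorConfig(
        seed=101, divergence=0.0, decoys_no_motif=2, decoys_orphan=3
    )
    gff, fasta, truth = generate_genome(cfg)
    genes = parse_genome(gff, fasta)
    return genes, truth


@pytest.fixture(scope="session")
def low_div_dataset():
    """One module per layout at 5% divergence (all sequences distinct)."""
    cfg = GeneratorConfig(
        seed=202, divergence=0.05, decoys_no_motif=2, decoys_orphan=3
    )
    gff, fasta, truth = generate_genome(cfg)
    genes = parse_genome(gff, fasta)
    return genes, truth


@pytest.fixture(scope="session")
def zero_div_survey(zero_div_dataset):
    genes, truth = zero_div_dataset
    result = run_survey(genes, SurveySettings(seed=101, bootstrap_replicates=25))
    return result, truth


@pytest.fixture(scope="session")
def low_div_survey(low_div_dataset):
    genes, truth = low_div_dataset
    result = run_survey(genes, SurveySettings(seed=202, bootstrap_replicates=25))
    return result, truth
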