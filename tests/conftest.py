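import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from htrscan.synthetic_data import SynthesisSpec, synth_genome


@pytest.fixture(scope="session")
def genome42():
    """The default synthetic genome: 4 genes per class + 20 decoys, seed 42."""
    return synth_genome(SynthesisSpec(seed=42))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, genome42):
    """One full pipeline run on the default synthetic genome (shared)."""
    from htrscan import genome_io
    from htrscan.pipeline import RunConfig, run_full_pipeline
    from htrscan.synthetic_data import synth_expression

    root = tmp_path_factory.mktemp("pipeline")
    paths = genome42.write(root / "genome")
    spec = SynthesisSpec(seed=42)
    matrix, expr_truth = synth_expression(spec.expression, seed=42)
    genome_io.write_expression_tsv(matrix, root / "expr.tsv")
    groups_path = root / "groups.tsv"
    with open(groups_path, "w") as fh:
        fh.write("tissue\tgroup\n")
        for t, g in spec.expression.tissue_groups.items():
            fh.write(f"{t}\t{g}\n")
    config = RunConfig(
        proteome=str(paths["proteome"]),
        cds=str(paths["cds"]),
        gff3=str(paths["gff3"]),
        queries=str(paths["queries"]),
        reference=str(paths["reference"]),
        expression_matrix=str(root / "expr.tsv"),
        tissue_groups=str(groups_path),
        outdir=str(root / "out"),
        seed=42,
        bootstrap_replicates=200,
    )
    result = run_full_pipeline(config)
    return {"config": config, "result": result, "expr_truth": expr_truth, "root": root}
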