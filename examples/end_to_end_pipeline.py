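"""The whole pipeline from the shell-style interface, in one script.

Equivalent to:

    cffvar --seed 1 --workspace ws simulate
    cffvar --seed 1 --workspace ws all

which generates a coherent synthetic scenario (cohort genotypes and depths,
risk-SNP panel, reference genotypes and site counts, annotations, gene
lists) and chains QC, SNP selection, the allele scan, the quartile burden
analysis, prioritization, the carrier/bootstrap comparison and the
high-risk screen, writing one TSV report per stage.
"""

import tempfile
from pathlib import Path

from click.testing import CliRunner

from cffvar.cli import main

workspace = Path(tempfile.mkdtemp()) / "ws"
runner = CliRunner()
for command in ("simulate", "all"):
    result = runner.invoke(main, ["--seed", "1", "--workspace", str(workspace), command])
    assert result.exit_code == 0, result.output
    print(result.output, end="")

print("\nreports written:")
for report in sorted(workspace.glob("*.tsv")):
    print(f"  {report.name}")
print("\ncarrier report (null scenario: cohort drawn from the reference):")
print((workspace / "carrier_report.tsv").read_text())
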