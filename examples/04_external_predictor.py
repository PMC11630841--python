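"""Wire an external structure predictor through the command adapter.

The adapter writes the query FASTA and template PDBs to a scratch directory,
runs a user-supplied command, and reads back the single model it leaves in the
output directory.  Here the 'predictor' is a stand-in shell command that
copies the first template -- enough to show the contract; swap in a real
ColabFold-style invocation for production use.
"""

import sys
import tempfile
import textwrap
from pathlib import Path

from famrescue import FamilySpec, PredictionRequest, generate_family
from famrescue.backends import CommandBackend

workdir = Path(tempfile.mkdtemp())
stub = workdir / "stub_predictor.py"
stub.write_text(textwrap.dedent("""\
    import shutil, sys
    from pathlib import Path
    fasta, template_dir, out_dir = map(Path, sys.argv[1:4])
    template = sorted(template_dir.glob('*.pdb'))[0]
    shutil.copy(template, out_dir / 'model.pdb')
"""))

backend = CommandBackend(
    command_template=(
        f"{sys.executable} {stub} {{fasta}} {{template_dir}} {{out_dir}} {{msa_flag}}"
    ),
    msa_mode_flag="--msa-mode mmseqs2",
    single_sequence_flag="--msa-mode single_sequence",
    workdir=workdir,
)

models, annotations, truth = generate_family(FamilySpec("PF_DEMO", n_members=5, seed=3))
query, template = models[0], models[1]
result = backend.predict(
    PredictionRequest(query.protein_id, query.sequence, "template_msa",
                      templates=(template,))
)
print(f"predicted model for {result.protein_id} in mode {result.mode}")
print(f"mean plDDT: {result.mean_plddt:.1f} (from the returned B-factor column)")
# A real predictor would honour the MSA flag and the templates; the adapter
# only cares that exactly one readable model lands in the output directory.
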