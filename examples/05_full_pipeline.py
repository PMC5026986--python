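"""Run the whole pipeline on the bundled worked-example tables.

Writes the budget summary, mixing attribution, qPCR abundances, detection
matrix and a human-readable report into ./pipeline_out, then prints the
report.  The same flow is available from the shell:

    throughfall fixture --name cj1_printed --out in/
    throughfall analyze --config run.yaml
"""

from pathlib import Path

from throughfall import RunConfig, make_fixture, run

out = Path("pipeline_out")
paths = make_fixture("cj1_printed", out / "input")
report = run(
    RunConfig(
        chemistry_csv=str(paths["chemistry"]),
        isotope_csv=str(paths["isotopes"]),
        qpcr_csv=str(paths["qpcr"]),
        detection_csv=str(paths["detections"]),
        out_dir=str(out / "results"),
    )
)
print(report.paths["report"].read_text())

# The report shows: classification 'nitrifying', the isotopic attribution
# 50.0-53.6 % vs the concentration-based 51.6 % (consistent), the implied
# delta-15N of the produced nitrate (negative, i.e. ammonium-derived), and
# 18.1 archaeal amoA copies per mL on the coarse filter.
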