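# Published source-data tables (not redistributed)

The persistence-length reproduction tests in
`tests/test_acceptance.py::TestPublishedPersistenceLengths` re-fit the
FRET versus polypeptide-length tables deposited alongside the original
tension-sensor calibration study of vinculin (the source-data files
accompanying its unloaded FRET-length figures and its dye-construct
force-spectroscopy figure).  Those tables are not redistributed here;
download them from the journal and convert to the length-series CSV
schema:

    context,repeat,n_repeats,efficiency_mean,efficiency_sem

as the files

    invitro_gpgga.csv      invitro_ggsggs.csv
    incellulo_gpgga.csv    incellulo_ggsggs.csv
    cy3cy5_unloaded.csv

plus `cy3cy5_force.csv` with columns

    force_pN,efficiency_mean,efficiency_sem

for the fluorescence-force spectroscopy points.  Without these files the
corresponding tests fail with an explanatory message; everything else in
the package is exercised on synthetic data.
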