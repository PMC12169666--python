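# GROMOS 54A7 emission variant.
#
# The RONS molecular parameters are identical in the 53A6 and 54A7
# frameworks; the variant differs only in the surrounding standard
# database: the Poger lipid types are part of the 54A7 main tables
# (under different names), and the Na+/Cl- ion Lennard-Jones parameters
# were updated in 54A7.  The updated ion self-parameters live in the
# engine's 54A7 main database and are not duplicated here: pair rows
# for the types listed under `engine_supplied` are therefore omitted
# from emitted 54A7 nonbonded tables, to be generated engine-side from
# the 54A7 tables together with the slot selections in c12_matrix.yaml.

engine_supplied: [NA+, CL-, OML, CH3L]

# Row-type renames applied when emitting 54A7 tables (lipid types are
# native to 54A7; names follow the 54A7 convention of dropping the
# lipid suffix in favour of the main-table type set).
renames: {}
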