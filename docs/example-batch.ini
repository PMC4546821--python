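# Example batch configuration: one section per data file.
# Run with:  pathviz batch docs/example-batch.ini

[liver-day1]
data = data/liver_stats.tsv
id_column = GeneID
; a column name holding per-row codes, or a fixed code such as L
system_code = SystemCode
species = Mus musculus
; a single .gpml file, or a directory of .gpml files
pathways = pathways/
mapping = mapping.tsv
; omit `criterion` for a visualisation-only entry
criterion = [P.Value_d1] < 0.05
; one line per visualised column:
;   <column> gradient <colour@value,...>
;   <column> rule <criterion> -> <colour>     (repeat to stack rules)
visualize =
    logFC_d1 gradient blue@-1,white@0,red@1
    P.Value_d1 rule [P.Value_d1] <= 0.05 -> green
out = results/liver-day1

[spleen-day1]
data = data/spleen_stats.tsv
id_column = GeneID
system_code = L
species = Mus musculus
pathways = pathways/
mapping = mapping.tsv
criterion = [P.Value_d1] < 0.05
visualize =
    logFC_d1 gradient blue@-1,white@0,red@1
out = results/spleen-day1
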