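# Packaged mini species lexicon: name<TAB>tax_id<TAB>source
# Pre-filtered demonstration/test lexicon; build production lexicons with
# `specieslink build-lexicon` from NCBI-Taxonomy-style name tables.
human	9606	taxonomy
humans	9606	taxonomy
homo sapiens	9606	taxonomy
mouse	10090	taxonomy
mice	10090	taxonomy
mus musculus	10090	taxonomy
rat	10116	taxonomy
rats	10116	taxonomy
rattus norvegicus	10116	taxonomy
yeast	4932	curated
saccharomyces cerevisiae	4932	taxonomy
baker's yeast	4932	taxonomy
drosophila melanogaster	7227	taxonomy
fruit fly	7227	taxonomy
zebrafish	7955	taxonomy
danio rerio	7955	taxonomy
xenopus laevis	8355	taxonomy
african clawed frog	8355	taxonomy
escherichia coli	562	taxonomy
e. coli	562	taxonomy
escherichia coli k-12	83333	taxonomy
e. coli k-12	83333	taxonomy
arabidopsis	3701	taxonomy
arabidopsis thaliana	3702	taxonomy
thale cress	3702	taxonomy
arabidopsis lyrata	59689	taxonomy
sus scrofa	9823	taxonomy
porcine	9823	curated
pig	9823	taxonomy
pigs	9823	taxonomy
bos taurus	9913	taxonomy
bovine	9913	curated
cattle	9913	taxonomy
chicken	9031	taxonomy
gallus gallus	9031	taxonomy
caenorhabditis elegans	6239	taxonomy
c. elegans	6239	taxonomy
chinese hamster	10029	taxonomy
cricetulus griseus	10029	taxonomy
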