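>INS P01308 insulin preproprotein (110 aa; signal 1-24, B chain 25-54, C peptide 57-87, A chain 90-110)
MALWMRLLPLLALLALWGPDPAAAFVNQHLCGSHLVEALYLVCGERGFFYTPKTRREAED
LQVGQVELGGGPGAGSLQPLALEGSLQKRGIVEQCCTSICSLYQLENYCN
>GCG P01275 glucagon preproprotein (180 aa; signal 1-20, GRPP 21-50, glucagon 53-81, GLP-1 98-128)
MKSIYFVAGLFVMLVQGSWQRSLQDTEEKSRSFSASQADPLSDPDQMNEDKRHSQGTFTS
DYSKYLDSRRAQDFVQWLMNTKRNRNNIAKRHDEFERHAEGTFTSDVSSYLEGQAAKEFI
AWLVKGRGRRDFPEEVAIVEELGRRHADGSFSDEMNTILDNLAARDFINWLIQTKITDRK
>SST P61278 somatostatin preproprotein (116 aa; signal 1-24, SST-28 89-116, SST-14 103-116)
MLSCRLQCALAALSIVLALGCVTGAPSDPRLRQFLQKSLAAAAGKQELAKYFLAELLSEP
NQTENDALEPEDLSQAAEQDEMRLELQRSANSNPAMAPRERKAGCKNFFWKTFTSC
>IAPP P10997 islet amyloid polypeptide preproprotein (89 aa; signal 1-22, amylin 34-70)
MGILKLQVFLIVLSVALNHLKATPIESHQVEKRKCNTATCATQRLANFLVHSSNNFGAIL
SSTNVGSNTYGKRNAVEVLKREPLNYLPL
>PPY P01298 pancreatic polypeptide preproprotein (95 aa; signal 1-29, PP 30-65, icosapeptide 69-88)
MAAARLCLSLLLLSTCVALLLQPLLGAQGAPLEPVYPGDNATPEQMAQYAADLRRYINML
TRPRYGKRHKEDTLAFSEWGSPHAAVPRELSPLDL
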