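>CHGA synthetic stand-in (457 aa; NOT the P10645 sequence: authentic length, signal 1-18, and dibasic sites flanking vasostatin-1 19-94, vasostatin-1/2 19-131, EA-92 134-225, LF-19/catestatin 358-390, GR-44 413-456)
MRSAAVLALLLCAGQVTALAKLLNLGTTKHSQQTENRWEEVNGVPVPAHPNVAIGDGQSS
RLMWSNQNELEHAQQSNLITKQAEREGPNPELSGKRLSESQGDKVDGIPEQQETQQLNEL
QEVLMFVEKDAKRELEAEPLEAEDINWALRAKELAVVKAPERTDAAYNAGRRREDANRLT
NRDMGRVYARAKLSPFEEEPSEKEVDDQDMRPRQEVWYMPLGLQPKRNSILTGYRQYQEK
IFYNNINFAAMVTVVRVTKLKPEELQSTLMRYESRPLGSFSGVLPGTETREDLGLAYLQQ
DTQEQIRSAEESQDEGRDGNFLNESSDHKRINAREVEIMWLEETQNTENVGKGYSKRLPQ
SSYRLRAGTVVTGALFIGWIRTYETGGSQSKRAWDRSSVQASTVDNEGPYKRGESLDTFK
ERFFVPDFHDVGDLDGSANKYDEAQQEGVDPGRTSFR
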