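>CORE_HRPKS class=HR-PKS synthetic core-enzyme reference
MGLYSYFEHYNLIGPPDGERMWWVLEIQMADSFVQRMFETFEAFFFTVDQEICYHRRSCS
CGTQRIGRQSAHPINSQLYQFFQVYMFNEHADVCKDNEAQETNNRRDFFYLCIEYIQSIY
DKICDCINDINCWPTCNKVHMMTEDSEIASVNWRPDGCQHWHNTRGKHKTPLDVSHMYLT
PLLHRPFNIKWGFKLVNTRYYLFELLQAYICFMAECAWTVLIKEVFGWFNHRDGMMAVIM
YYGLLVVFHYEQTIFIIHEDIRMVMMTIRVMNAAKEKEKTSDIVQITHYPGTTQWMAFCR
DYKEPHPRWTPIYNDYCDICAMKANMAHYYRSWHHIDMWWSFSSRKPLFNVGLLVCDLRW
LFNWGGNYHIYHPGVVNITPQKYDLHCMRAAILLTNRVHNKAIAYRHQEMPLSLINHPRF
>CORE_NRPKS class=NR-PKS synthetic core-enzyme reference
MWWVWANGQWTKTAYWRVYTVKHIYLVCFTDAHGPHYENKEIFWISFFYYHVWHISDKNS
LVATSWGFEGIWCCLYSCYRMYKRFITIIFYADFQYWYVTMWHDRLCGQLAAMMMWPQLH
QNCKGDDPEGMLKHKTNTSMMMSVDFEFMWFNTWTCRNHSCEFDYQYYMPEMTVKCYNHW
CVRLLCRPNYQDWEMKNDLACWMEPSTCCGNTDQITYCKEFGEGPIVHHGTKHARVTGGN
NRLPSSWPKMAKGERKPQWCQTTQVRYYYAVLANYMERAINPLQYEINLIPVDMCRLTYP
CAKYTSCMSFNLRVRNSPFCKEFPMCIFCPFQGECLHYTKEWPLYWEKQFEGLYVKSLAY
NLISDEEMPQLINEVTMSRKTTSYAQEEYMKESMAGGIRL
>CORE_NRPS class=NRPS synthetic core-enzyme reference
MVTMNMKEQSGDYQFAVNDPHCFWPPLIHLTMMHAINYAATHVMYGNSQGPDSELMSMCL
FVWCVFGWWHHTRQDCINWCYMYVYWNCSIVIQMFTHAKHSTWKSTDPCHVSEDEGNMSQ
CSLKMQFQFTMTAAGFDSSYKWTEEYTGFKLLAYDILQPRFHSMWPPNKMVNNRFVAGEH
YRCSPNIYRNPPGGHFKIDNRGQGHWVDLYTKRHKWAVCWLMCQTFKLCVCSSFFIMPWM
SQNEHVHQGNPCHTCWPQSHHFLWTIVWAMYNQPNQPMRGLNNFMQCPQHQDMSGPDPCT
MAASAKIYSQHADPHMFQIGRRHDNCGTFFNVLRTWFILFHWSRNCEKMTKEWGPDELHK
LPTKIMNKDGPKVMHFCPAMVTSHILVDPWDGSAQSMAGQRVEFDQEHGVPLNVCYHGNQ
GCFDWFQQQW
>CORE_NRPSL class=NRPS-like synthetic core-enzyme reference
MSQVQCDYMTNRTCRQNHSILLRVPYVVMLTGKNDHRELPRLIVQIHFFHITTIKPRVAM
IFWVTDYINRFCWQVRNDCLHFKLTWCSTLTMPWGTGATHYCKMEVDDECDDRRWMFLVN
NKKKPCSFKMHFFPAAEENHLFSEHTPYDNDNQRQACYMGMVCQMVWFQAKQDRCLKVNS
VECCEYHRDHCSYRYCNFQKSMNNLYDHKVDGYEQFRLTPFSQHVWTPTTTRGQWVLFGQ
AECALMVAIQLCKQEPMDVMHRWYGEGMGKYEWHKWDWAPNCFCDMFCTQYAYDMWYVEN
>CORE_TS class=terpene_synthase synthetic core-enzyme reference
MITCIITMHFFPVSALNAEHKPGCMKCADNAIPSGKEFAGKSYDSLRQNPNMVGFEQSGK
IQVFFQWKMAMPAMCPGMWYPPSDWYTEGRYLLEIRADHFDGNILDHCVIQFSCDKKECV
VDSGMYIFPVFTEQKFEWQAEHGMIADEYYPYTMQEPDCKQMSEIKLALFREPQMTFDDP
PMRMKSFMLMCPKMGNQPLKGILVLRPLDNACPFDKVNNAHKSTSRTVMWKAYHLMSSEI
FAAWVLCAPKQGVIYGAFFFPFPMRFNMIRAEKQDYKGYIRVNDRFASECHGTAIRQYYQ
PFKSAPIPKPLNVLIEANQIEIVALTCAIF
>CORE_PT class=prenyltransferase synthetic core-enzyme reference
MMGAGRPNMIMHGNWFIQIISWYARGPIMEIFQVSKWPTTCYQYRINPPMYMWMRWIWSC
VYICWERVRMIFVNMLTKDIDFSMWQVYEGHSSCTMPEKMNDCLCAWLETDMVQTNDYFE
VHYSGHNRVMMNFSHQCEAYLIEYEMPGVNEEMFAESHMPVNMMEAAGQPAIINDPNKAS
IFPHGCCCPKIPQMWEQFDNANKICDDNWQGPAMFCDMWRFKWDVYVGICSYQWELDPWV
TCHMFYLFHMQHYQHIYVSWWTTKWDMHEMWKVCRMWCQWKREKPMDQGTTMKWCKIHFK
SAAMPVYYQS
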