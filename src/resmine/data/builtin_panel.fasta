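>HK01 synthetic hook bait
MMCKKFAWVAAMWNRQKCVCFCWAWSRTQEDDPHTAYSVCFRWRFQNCGWVEIFCHAYKP
IHGFPMKKGQLYGYQGYPMWTPLMIKDLGLPNPHDRANILGVLIFRYHGAKCVLRASVPY
ICELPRISANYSDEMVAKGSKYWDWRGLQAWLVDKDSNPIFLKPQMPMRLKMTNEKYDME
IGCTARTASASDSAGNEVHGFEHPYMFRVRRRWPKACCCIEWEMPHETWHTAWPMQHQKH
ERVFTSPNETGTNCRDFNGGRKMHEFFNCPIHFEHTSTSYFGKYKQITRHRIKFHRAHNS
WINCGGYEMIEFSQMPQGQGQVWLPSLARAWRDMVRITLGTDMIYVVCRVMTWAPMMDYF
TLRLNKWVVFTWWHPKANPY
>HK02 synthetic hook bait
MIEPVGRSALKGLIKWYKFPQWCLQKADKWGYMHWGKDHDTDTFHWAKKYVKFVGAQPEQ
CMPDEAYWGMYEIVTQCDGEACRPLDINVTYYRCKIYRFSEFLTPGIDYGHVTVSIYKAN
YKTRMGPMLMDYFHSLWYNGCFCRYPRSGWMASFCIMHDGTCCPPLSTMVIPQCAYLYNV
NYEKAVCNIQHDNMFGNCEMYNVKKSVMCCIHAVNWWGQHRRHRFTTTDYSVNVTQNPSH
WGIWLTNVKVHGARIYICHYDDCCSNCQCYETYWDYAVCEYTRYWSCYVRFTSPSRMTVR
GWVWFPACPFKCKRCMKFPWYHVNTAQDMSFCTYMWYDEE
>HK03 synthetic hook bait
MRSLPQWRDDVRCNAWDMGGMIKVKWINWEMCICCSYRHEVTIYCLIDPENSKCMNAQWY
HDVTKKTPSAQINQTAHRECWWSVDYISKIITDCRLGTHMIWHIIGIMILRRLAIPLNSW
RRKINEEQMFHIGALNIVEKFKHKQPRNQYLFIRTMFICIWRAWRPGNYCANKTKCPRSY
RNNSSMRRGMEFRLHVQGRKCCMECSHHPALAFDVTGIMYHQLYGWQFTYSFRGTEFHEQ
DEAGSRGQERDPQSGVGWWKCEDLSRKDDPNGDYRPTCNI
>HK04 synthetic hook bait
MSEYPLGMMLKLDNHAVFGNMGELDWALWPHNDQPSPMNEYKCRFPWLRYPIRLSFMHNN
IKHRVGNSWHKEFVNHSYPDDADWGIWYCCGWGVRFCQWFGHEHEEQLFCCFKDQCWRHC
SKGHDLSGVLGRCEFVHANKKESTYHNGYWYAGYMCMKRFHDTHRFYDKIIIENNGSHLL
TPCKAIGTFEYDPPDSEICLGGVLKCFNSRLSNRQWDNYQEMGEKDFCIAHFFFIPIIEL
CAPGMVNNMLYSCKYMLMLGANYFQHALVGFMYCKTYSSRCMLVVFDAHGSVVSQHIVNM
>HK05 synthetic hook bait
MESDRWKHLCYFFWAIRMEGCMNYLMHAKCDAWGPLIIMDHTSTLYNQAFVCYCKRNFLN
NTDSGSYMMFDNMEFTAMGNIPRFTWPPHIQTFLRSPSIARRFPCHDWPTNDASDWSWWI
GFQVDEDKNVWNDFNHLISMWCENAEQQYHHISHQWMVSNKARHWYSWKKQNWKCHEVMC
MGEQNSECTFPKLQPASYWEPFVPFLQQIDHRKEWLEGQYYDELIWRYWRIHHSFPGDYG
MSPGIKISALNGSSVGEHVYQIFMDRYMYLKFNIIFKYRCHRNAVWDGIFGLPDDQGLGG
VACKNLPTGFLDWLPTAWDMLCAWPLPEWA
>HK06 synthetic hook bait
MVPKTPSYWAQQATQHDRGICEDFPTEQANFSRLARVVSDSQWFQHWCTAAQTLECRTMS
VKVCEIKPVCRSRAWGFNTIALERWTDDDKDRRDYYVWPLQTDICYWFRYAKPPEEKLVN
YAHMAFFVGTCYKYYSAKCPRLRGFVINRWEQGMKVHIHTHKIAENAYDFWQKCRAMHMM
MFRGLDAILSPHCLWGRCFSVVHISNPMNRDMWKQVTDEWCPCNYPHGQWIEQNQNHDGC
WSMALFLMQQAFNDAIYTSIMFPLTFMGKTCGQAGTLDTSRYGRTSMHHVVSGFFRPEGS
KFNPVGTPWRSLIFNDARDQHKQDLWWYWWHGRQVHTGPIHFDATISSNG
>HK07 synthetic hook bait
MYQTWQYMWKSTLKMYNAMHKSMYSQPEAPSVEEDFMTDRNTQSLPYNEDNKPDGMDQPH
MHGNVDKVFEHRRALIFHTMFRKHQEPLTEPNPRQPLIYWKCFHDTKTTIYQHGQDWVSG
RKQWLDGHLQVDGGQYDYVFKGKSHRKGTRESVLAKHADWWFKASWTIDEHYKEPHKPAT
HQYDFPYEWLDINFAYFWHKKVTDNMITWMLCKFIEWEEGGHFWSDQFLPENVCPKLAHR
IKICPHGDFGVCFMYKNDTEYNGSVTYYDLLWVDTPRQWDIKFNPDNMWPAGPLPDIPCM
EPLWVPDIANMHCFGRCPELQFIKCYQAQSMFFSTWIDYENMHWGSLLNMQNTFMQTNRM
FNGKMRAELASVADYVSHHVWIWRPHYDSQWFCVNSIFRC
>HK08 synthetic hook bait
MMNGICYMRWYIFWWYIVCHLINSNHFRAHEKVLPMARSHTQMPTRIRFFPHTESQWMQN
GQRTPVNFVCYGCDVHGGERFQWNGYPLLKRHKLIWKLCLLWPTADRLISQWTQDVWDKM
SVRKKYPGHPGNMIPSWNLGMMNMNTMVMRVGMYCIICVTTTMFTDVMHACRSWHTRRND
CDKTCDCKFTAPENVHRQLLHQAQMYFWAIMGKESLKDRTLSQPIGPNASLNTLYVVGHK
FHKDTIPTTSSQDVKWLIGI
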