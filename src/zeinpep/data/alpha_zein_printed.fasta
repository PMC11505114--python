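>P06674 Zein-alpha 19A2
KIFCFLMLLGLSASAATATIFPQCSQAPITSLLPPYLSPAVSSVCENPILQPYRIQQAIA
AGILPLSPLFLQQPSALLQQLPLVHLLAQNIRAQQLQQLVLGNLAAYSQQHQFLPFNQLA
ALNSAAYLQQQLPFSQLAAAYPQQFLPFNQLAALNSAAYLQQQQLPPFSQLADVSPAAFL
TQQQLLPFYLHAAPNAGTVLQLQQLLPFDQLALTNPTAFYQQPIIGGALF
>P06676 Zein-alpha 19C1
MATKIFSLLMLLALSACVANATIFPQCSQAPIASLLPPYLPSMIASVCENPALQPYRLQQ
AIAASNIPLSPLLFQQSPALSLVQSLVQTIRAQQLQQLVLPLINQVALANLSPYSQQQQF
LPFNQLSTLNPAAYLQQQLLPFSQLATAYSQQQQLLPFNQLAALNPAAYLQQQILLPFSQ
LAAANRASFLTQQQLLPFYQQFAANPATLLQLQQLLPFVQLALTDPAASYQQHIIGGALF
>P06678 Zein-alpha 19D1
MAAKIFALLALLALSANVATATIIPQCSQQYLSPVTAARFEYPTIQSYRLQQAIAASILR
SLALTVQQPYALLQQPSLVNLYLQRIVAQQLQQQLLPTINQVVAANLDAYLQQQQFLPFN
QLAGVNPAAYLQAQQLLPFNQLVRSPAAFLLQQQLLPFHLQVVANIAAFLQQQQLLPFYP
QVVGNINAFLQQQQLLPFYPQDVANNVAFLQQQQLLPFSQLALTNPTTLLQQPTIGGAIF
>P04705 Zein-alpha PZ19.1
MAAKIFCLIMLLGLSASAATASIFPQCSQAPIASLLPPYLSPAMSSVCENPILLPYRIQQ
AIAAGILPLSPLFLQQSSALLQQLPLVHLLAQNIRAQQLQQLVLANLAAYSQQQQLPLVH
LLAQNIRAQQLQQLVLANLAAYSQQQQFLPFNQQLAAAYPRQFLPFNQLAALNSHAYVQQ
>P06679 22 kDa alpha-zein 8b
LALLALLALFVSATNAFIIPQCSLAPSAIIPQFLPPVTSMGFEHLAVQAYRLQQALAASV
LQQPINQLQQQSLAHLTIQTIATQQQQQFLPSVSQLDVVNPVAYLQQQLLASNPLALANV
AAYQQQQQLQQFLPALSQLAMVNPAAYLQQQQLLSSSPLAVGNAPTYLQQQLLQQIVPAL
TQLAVANPAAYLQQLLPFNQLTVSNSAAYLQQRQQLLNPLEVPNPLVAGFLQQQQLLPYS
QFSLMNPALSWQQPIVGGAIF
>Q94IM1 22 kDa alpha-zein 14
MATKILSLLALLALFASATNASIIPQCSLAPSSIIPQFLPPVTSMAFEHPAVQAYRLQQA
IAASVLQQPIAQLQQQSLAHLTIQTIATQQQQQFLPALSHLAMVNPIAYLQQQLLASNPL
GLANVVANQQQQQLQQFLPALSQLAMVNPAAYLQQQQLLSSSPLAVANAPTYLQQELLQQ
IVPALTQLAVANPVAYLQQLLPFNQLTMSNSVAYLQQRQQLLNPLAVANPLVAAFLQQQQ
LLPYNRFSLMNPVLSRQQPIVGGAIF
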