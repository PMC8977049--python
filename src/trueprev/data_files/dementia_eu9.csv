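id,study,country,years,positive,n
1,Ravaglia et al.,Italy,1999,60,961
2,Tognoni et al.,Italy,2000,100,1662
3,Gascon-Bayarri et al.,Spain,2002,165,1754
4,Fish et al.,UK,2003,88,1665
5,Bermejo-Pareja et al.,Spain,1994-5 1997-8,306,5278
6,Mathillas et al.,Sweden,2000-2 2005-7,287,895
7,Tola-Arribas et al.,Spain,2009-10,184,2170
8,Lucca et al.,Italy,2009-10,894,2501
9,Perquin et al.,Luxembourg,2008,53,1377
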